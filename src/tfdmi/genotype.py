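"""Quaternary two-state genotype-phenotype map for protein-DNA binding.

A transcription factor (TF) and its DNA binding site (TFBS) are modelled as a
pair of sequences of equal length ``ell`` over the alphabet {A, C, G, T}.  The
protein "sequence" records, per interface position, the category of amino acid
by its preferred partnering base, so both loci live in the same four-letter
space and mutate identically.  Binding is described by the two-state
(match/mismatch) approximation: every mismatched position contributes an
additive penalty ``delta_eps`` (kBT) to the specific binding free energy,

    dG(r) = delta_eps * r,      r = Hamming distance protein vs DNA,

measured from the perfect binder (the per-match zero point is absorbed into
the zero of energy).  The specific mode competes thermodynamically with a
sequence-independent electrostatic mode of free energy ``ell * delta_eps_ns``;
once ``dG(r)`` exceeds that, specific recognition is lost.  The largest viable
mismatch count is therefore

    r* = floor(ell * delta_eps_ns / delta_eps),

with ``dG* = delta_eps * r*`` the corresponding energy cliff.

The module also provides the exact combinatorics of the map: the number of
(protein, DNA) pairs at mismatch class r is

    Omega(r) = 4**ell * C(ell, r) * 3**r

(an exact integer), and the sequence entropy S(r) = ln Omega(r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "BindingModel",
    "TFGenotype",
    "hamming_distance",
    "binding_energy",
    "critical_mismatches",
    "is_viable",
    "degeneracy",
    "sequence_entropy",
    "classify_one_step_mutants",
    "one_step_mutants",
    "random_genotype_at_distance",
    "seq_to_array",
    "array_to_seq",
    "write_fasta",
    "read_fasta",
]


def _validate_sequence(s: str) -> None:
    if not s:
        raise ValueError("sequence must be non-empty")
    bad = set(s) - set(ALPHABET)
    if bad:
        raise ValueError(f"sequence contains letters outside {{A,C,G,T}}: {sorted(bad)!r}")


def seq_to_array(s: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    _validate_sequence(s)
    return np.frombuffer(s.encode().translate(bytes.maketrans(b"ACGT", bytes(range(4)))), dtype=np.uint8).copy()


def array_to_seq(a: np.ndarray) -> str:
    """Decode a uint8 array back to an ACGT string."""
    return "".join(ALPHABET[int(x)] for x in a)


@dataclass(frozen=True)
class TFGenotype:
    """A TF protein-preference sequence paired with its DNA binding site."""

    protein: str
    dna: str

    def __post_init__(self) -> None:
        _validate_sequence(self.protein)
        _validate_sequence(self.dna)
        if len(self.protein) != len(self.dna):
            raise ValueError(
                f"protein and dna must have equal length ({len(self.protein)} != {len(self.dna)})"
            )

    @property
    def ell(self) -> int:
        return len(self.protein)

    @property
    def mismatches(self) -> int:
        return hamming_distance(self.protein, self.dna)


@dataclass(frozen=True)
class BindingModel:
    """Parameters of the two-state binding map.

    Parameters
    ----------
    ell
        Number of interface positions (binding-site length).
    delta_eps
        Energy penalty per mismatch, in kBT.  Default 3 kBT.
    delta_eps_ns
        Nonspecific (electrostatic) binding free energy per position relative
        to the optimal binder, in kBT.  Default 1.5 kBT.
    r_star_override
        Optional integer override of the viability threshold r*, for
        sensitivity analyses.  By default r* = floor(ell*delta_eps_ns/delta_eps).
    """

    ell: int
    delta_eps: float = 3.0
    delta_eps_ns: float = 1.5
    r_star_override: int | None = None

    def __post_init__(self) -> None:
        if self.ell < 1:
            raise ValueError("ell must be a positive integer")
        if self.delta_eps <= 0:
            raise ValueError("delta_eps must be positive")
        if self.delta_eps_ns < 0:
            raise ValueError("delta_eps_ns must be non-negative")
        if self.r_star_override is not None and not 0 <= self.r_star_override <= self.ell:
            raise ValueError("r_star_override must lie in [0, ell]")

    @property
    def r_star(self) -> int:
        """Largest viable mismatch count (inviability cliff is at r > r*)."""
        if self.r_star_override is not None:
            return self.r_star_override
        return min(self.ell, math.floor(self.ell * self.delta_eps_ns / self.delta_eps))

    @property
    def dG_star(self) -> float:
        """Binding energy at the cliff, delta_eps * r*, in kBT."""
        return self.delta_eps * self.r_star

    @property
    def dG_ns(self) -> float:
        """Free energy of the nonspecific mode, ell * delta_eps_ns, in kBT."""
        return self.ell * self.delta_eps_ns


def hamming_distance(a: str | Sequence[int] | np.ndarray, b: str | Sequence[int] | np.ndarray) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} != {len(b)}")
    if isinstance(a, str) and isinstance(b, str):
        return sum(x != y for x, y in zip(a, b))
    return int(np.count_nonzero(np.asarray(a) != np.asarray(b)))


def binding_energy(g: TFGenotype, m: BindingModel) -> float:
    """Specific binding free energy dG = delta_eps * r, in kBT."""
    if g.ell != m.ell:
        raise ValueError(f"genotype length {g.ell} does not match model ell={m.ell}")
    return m.delta_eps * g.mismatches


def critical_mismatches(m: BindingModel) -> int:
    """The viability threshold r* = floor(ell * delta_eps_ns / delta_eps)."""
    return m.r_star


def is_viable(r: int, m: BindingModel) -> bool:
    """True iff mismatch class r is viable (r <= r*)."""
    if not 0 <= r <= m.ell:
        raise ValueError(f"r={r} outside [0, ell={m.ell}]")
    return r <= m.r_star


def degeneracy(r: int, m: BindingModel) -> int:
    """Exact number of (protein, dna) pairs with Hamming distance r.

    Omega(r) = 4**(2 ell) * C(ell, r) * (3/4)**r * (1/4)**(ell-r)
             = 4**ell * C(ell, r) * 3**r,  an exact integer.
    """
    if not 0 <= r <= m.ell:
        raise ValueError(f"r={r} outside [0, ell={m.ell}]")
    return 4**m.ell * math.comb(m.ell, r) * 3**r


def sequence_entropy(r: int, m: BindingModel) -> float:
    """Sequence entropy S(r) = ln Omega(r), in nats (log-gamma form, safe for large ell)."""
    if not 0 <= r <= m.ell:
        raise ValueError(f"r={r} outside [0, ell={m.ell}]")
    ell = m.ell
    log_comb = math.lgamma(ell + 1) - math.lgamma(r + 1) - math.lgamma(ell - r + 1)
    return ell * math.log(4.0) + log_comb + r * math.log(3.0)


def one_step_mutants(g: TFGenotype) -> Iterator[tuple[str, int, str, TFGenotype]]:
    """Yield all 6*ell single-letter mutants as (locus, position, new_letter, mutant)."""
    for locus, seq in (("protein", g.protein), ("dna", g.dna)):
        for pos, cur in enumerate(seq):
            for letter in ALPHABET:
                if letter == cur:
                    continue
                new = seq[:pos] + letter + seq[pos + 1 :]
                if locus == "protein":
                    yield locus, pos, letter, TFGenotype(new, g.dna)
                else:
                    yield locus, pos, letter, TFGenotype(g.protein, new)


def classify_one_step_mutants(g: TFGenotype, m: BindingModel) -> tuple[int, int, int]:
    """Count the 6*ell one-step mutants by their effect on the mismatch number.

    Returns (n_down, n_same, n_up): mutants decreasing, preserving and
    increasing r.  By explicit enumeration; the closed forms are
    n_down = 2r, n_same = 4r, n_up = 6(ell - r).
    """
    if g.ell != m.ell:
        raise ValueError("genotype length does not match model")
    r = g.mismatches
    n_down = n_same = n_up = 0
    for _, _, _, mut in one_step_mutants(g):
        dr = mut.mismatches - r
        if dr < 0:
            n_down += 1
        elif dr == 0:
            n_same += 1
        else:
            n_up += 1
    return n_down, n_same, n_up


def random_genotype_at_distance(r: int, m: BindingModel, rng: np.random.Generator) -> TFGenotype:
    """Draw a uniform (protein, dna) pair with exactly r mismatches.

    The protein is uniform over the 4**ell sequences; the dna copies it except
    at r uniformly chosen positions, each set to a uniform non-matching letter.
    This is the uniform law within the r-class (the stationary distribution is
    uniform over sequences of equal r).
    """
    if not 0 <= r <= m.ell:
        raise ValueError(f"r={r} outside [0, ell={m.ell}]")
    protein = rng.integers(0, 4, size=m.ell, dtype=np.uint8)
    dna = protein.copy()
    if r:
        pos = rng.choice(m.ell, size=r, replace=False)
        dna[pos] = (dna[pos] + rng.integers(1, 4, size=r, dtype=np.uint8)) % 4
    return TFGenotype(array_to_seq(protein), array_to_seq(dna))


# --- FASTA I/O ------------------------------------------------------------
#
# Each genotype is stored as two records:
#   >lineage<id>|locus=protein|t=<mu0 t>
#   >lineage<id>|locus=dna|t=<mu0 t>

def _header(lineage_id: str | int, locus: str, t: float) -> str:
    return f"lineage{lineage_id}|locus={locus}|t={t:.10g}"


def write_fasta(path, entries: Sequence[tuple[str | int, TFGenotype, float]]) -> None:
    """Write genotypes to FASTA, two records per genotype."""
    records = []
    for lineage_id, g, t in entries:
        records.append(SeqRecord(Seq(g.protein), id=_header(lineage_id, "protein", t), description=""))
        records.append(SeqRecord(Seq(g.dna), id=_header(lineage_id, "dna", t), description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, TFGenotype, float]]:
    """Read genotypes written by :func:`write_fasta`.

    Returns a list of (lineage_id, genotype, t).  Validates the 4-letter
    alphabet and that each lineage has exactly one protein and one dna record.
    """
    by_lineage: dict[str, dict[str, tuple[str, float]]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.id.split("|")[1:] if "=" in kv
        )
        lineage = rec.id.split("|", 1)[0]
        locus = fields.get("locus")
        if locus not in ("protein", "dna"):
            raise ValueError(f"FASTA record {rec.id!r} lacks a locus=protein|dna field")
        seq = str(rec.seq).upper()
        _validate_sequence(seq)
        t = float(fields.get("t", 0.0))
        if lineage not in by_lineage:
            by_lineage[lineage] = {}
            order.append(lineage)
        if locus in by_lineage[lineage]:
            raise ValueError(f"duplicate {locus} record for {lineage}")
        by_lineage[lineage][locus] = (seq, t)
    out = []
    for lineage in order:
        loci = by_lineage[lineage]
        if set(loci) != {"protein", "dna"}:
            raise ValueError(f"{lineage} must have exactly one protein and one dna record")
        (p, tp), (d, td) = loci["protein"], loci["dna"]
        if tp != td:
            raise ValueError(f"{lineage}: protein and dna records carry different times")
        lineage_id = lineage[len("lineage"):] if lineage.startswith("lineage") else lineage
        out.append((lineage_id, TFGenotype(p, d), tp))
    return out
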