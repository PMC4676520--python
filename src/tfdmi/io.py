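"""Run configuration, result serialization and reproducibility metadata.

A :class:`RunConfig` gathers every model, selection and experiment parameter
plus the master seed; it round-trips losslessly through a YAML file (see
``docs/config.schema.yaml``) and resolves into the domain objects.  All
tables are written as TSV (tab-separated, '.' decimal, LF endings, floats at
10 significant digits) with a JSON metadata sidecar embedding the resolved
configuration and seed, so a rerun with the same config reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype import BindingModel
from .landscape import SelectionParams

__all__ = ["RunConfig", "load_config", "write_tsv", "write_json", "ResultBundle"]

_DEFAULT_NE = 1000.0


@dataclass
class RunConfig:
    """Resolved parameters of a run (defaults: ell=10, deps=3, deps_ns=1.5, M=1e5)."""

    ell: int = 10
    delta_eps: float = 3.0
    delta_eps_ns: float = 1.5
    r_star_override: int | None = None
    Ne: float | None = None
    kappa_F: float | None = None
    scaled_size: float | None = None
    mu0: float = 1.0
    M: float = 1e5
    ancestor_mode: str = "equilibrium"
    dmi_mode: str = "first_passage"
    rate_form: str = "full"
    n_replicates: int = 1000
    t_max: float = 500.0
    grid_min: float = 1e-4
    points_per_decade: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        explicit = self.Ne is not None or self.kappa_F is not None
        if explicit and self.scaled_size is not None:
            raise ValueError("give either (Ne, kappa_F) or scaled_size, not both")
        if explicit:
            if self.Ne is None or self.kappa_F is None:
                raise ValueError("Ne and kappa_F must be given together")
        elif self.scaled_size is None:
            self.scaled_size = 0.04  # drift-regime default
        if self.scaled_size is not None:
            self.Ne = _DEFAULT_NE
            self.kappa_F = self.scaled_size / (4.0 * self.Ne)
        else:
            self.scaled_size = 4.0 * self.Ne * self.kappa_F
        if self.ancestor_mode not in ("equilibrium", "fixed-r", "user"):
            raise ValueError(f"ancestor_mode: unknown value {self.ancestor_mode!r}")
        if self.dmi_mode not in ("first_passage", "instantaneous"):
            raise ValueError(f"dmi_mode: unknown value {self.dmi_mode!r}")
        if self.rate_form not in ("full", "scaled"):
            raise ValueError(f"rate_form: unknown value {self.rate_form!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates: must be >= 1")
        if self.t_max <= 0:
            raise ValueError("t_max: must be positive")
        if self.M < 1:
            raise ValueError("M: must be >= 1")

    def binding_model(self) -> BindingModel:
        return BindingModel(
            ell=self.ell,
            delta_eps=self.delta_eps,
            delta_eps_ns=self.delta_eps_ns,
            r_star_override=self.r_star_override,
        )

    def selection_params(self) -> SelectionParams:
        return SelectionParams(kappa_F=self.kappa_F, Ne=self.Ne, mu0=1.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Unknown keys raise with the offending key named; overrides equal to None
    are ignored (so CLI flags left unset fall through to the file/defaults).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with a header row, fixed column order and 10-significant-digit floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


@dataclass
class ResultBundle:
    """A set of tables plus metadata, written together under one directory."""

    tables: dict[str, pd.DataFrame]
    meta: dict
    fasta: list | None = None  # entries for genotype.write_fasta

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables.items():
            p = outdir / f"{name}.tsv"
            write_tsv(df, p)
            written.append(p)
        p = outdir / "meta.json"
        write_json(self.meta, p)
        written.append(p)
        if self.fasta is not None:
            from .genotype import write_fasta

            p = outdir / "genotypes.fasta"
            write_fasta(p, self.fasta)
            written.append(p)
        return written
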