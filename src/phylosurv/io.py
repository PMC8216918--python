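"""Trait-table I/O, configuration and the packaged pinniped survival data.

Trait tables are UTF-8 comma-separated files with a header row:

    species,rate,rate_se,covariate,covariate_se

``rate_se`` may be replaced (or supplemented) by ``rate_ci_low`` /
``rate_ci_high``; a 95% confidence interval is converted to a standard
error by the normal approximation se = width / 3.92, and the conversion is
flagged in the record provenance.  Rows without any uncertainty estimate
for the survival rate are an error: the analysis is built on the inclusion
rule that every rate carries an uncertainty estimate.

The packaged fixture ships male pinniped survival rates (with SEs or 95%
CIs) at three life stages — yearling, sexual maturity, social maturity —
compiled from published mark-recapture studies.  It contains survival data
only; covariates must be supplied by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mcmc import Chains, McmcConfig
from .model import Priors, SpeciesRecord

__all__ = [
    "read_species_table",
    "records_from_frame",
    "write_species_table",
    "load_fixture",
    "fixture_frame",
    "chains_from_csv",
    "RunConfig",
]

#: 95% normal interval width in standard errors
_CI95_WIDTH = 2.0 * 1.959963984540054

STAGES = ("yearling", "sexual", "social")


def _se_from_row(row, context: str) -> tuple[float, str]:
    se = row.get("rate_se")
    if se is not None and np.isfinite(se) and se > 0:
        return float(se), "reported_se"
    lo, hi = row.get("rate_ci_low"), row.get("rate_ci_high")
    if lo is not None and hi is not None and np.isfinite(lo) and np.isfinite(hi):
        if not hi > lo:
            raise ValueError(f"{context}: confidence interval bounds out of order ({lo}, {hi})")
        return float((hi - lo) / _CI95_WIDTH), "derived_from_ci"
    raise ValueError(
        f"{context}: no uncertainty estimate for the survival rate (rate_se or "
        "rate_ci_low/rate_ci_high required) — rates without an uncertainty "
        "estimate are excluded by the inclusion rule"
    )


def records_from_frame(df: pd.DataFrame, require_covariate: bool = True) -> list[SpeciesRecord]:
    """Validated species records from a trait table DataFrame."""
    if "species" not in df.columns or "rate" not in df.columns:
        raise ValueError("trait table needs 'species' and 'rate' columns")
    records = []
    for _, row in df.iterrows():
        d = row.to_dict()
        species = str(d["species"])
        se, _src = _se_from_row(d, species)
        W, var_u = 0.0, 0.0
        if "covariate" in d and d["covariate"] is not None and np.isfinite(d["covariate"]):
            W = float(d["covariate"])
            cse = d.get("covariate_se", 0.0)
            var_u = float(cse) ** 2 if cse is not None and np.isfinite(cse) else 0.0
        elif require_covariate:
            raise ValueError(f"{species}: covariate value required for fitting")
        records.append(SpeciesRecord(species=species, D=float(d["rate"]), se_D=se,
                                     W=W, var_u=var_u))
    return records


def read_species_table(path, require_covariate: bool = True) -> list[SpeciesRecord]:
    """Read and validate a trait CSV into species records."""
    return records_from_frame(pd.read_csv(path), require_covariate=require_covariate)


def write_species_table(records: list[SpeciesRecord], path) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in records],
            "rate": [r.D for r in records],
            "rate_se": [r.se_D for r in records],
            "covariate": [r.W for r in records],
            "covariate_se": [float(np.sqrt(r.var_u)) for r in records],
        }
    ).to_csv(path, index=False)


def fixture_frame() -> pd.DataFrame:
    """The packaged pinniped survival table (all stages, raw columns)."""
    with resources.files("phylosurv.data").joinpath("pinnipeds.csv").open() as fh:
        return pd.read_csv(fh)


def load_fixture(stage: str = "social") -> list[SpeciesRecord]:
    """Survival records for one life stage from the packaged pinniped data.

    The social-maturity subset has 12 species, sexual maturity 11 and
    yearling 8 (species without an uncertainty-carrying estimate at a stage
    are absent).  Covariates are zero-filled: supply body-length data before
    fitting a regression.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    df = fixture_frame()
    sub = df[df["stage"] == stage]
    return records_from_frame(sub, require_covariate=False)


def chains_from_csv(path, cri_level: float = 0.95) -> Chains:
    """Rebuild a Chains object from its long-format CSV export."""
    df = pd.read_csv(path)
    if "chain" not in df.columns or "iteration" not in df.columns:
        raise ValueError("chains CSV needs 'chain' and 'iteration' columns")
    chains_ids = sorted(df["chain"].unique())
    n_keep = int(df["iteration"].max()) + 1
    params = [c for c in df.columns if c not in ("chain", "iteration") and "[" not in c]
    draws = {}
    for name in params:
        arr = np.empty((len(chains_ids), n_keep))
        for ci, c in enumerate(chains_ids):
            sub = df[df["chain"] == c].sort_values("iteration")
            arr[ci] = sub[name].to_numpy()
        draws[name] = arr
    cfg = McmcConfig(n_chains=len(chains_ids), n_adapt=0, n_burn=0, thin=1,
                     n_keep=n_keep, cri_level=cri_level, monitor=tuple(params))
    return Chains(draws=draws, config=cfg, seed=0, species=[])


@dataclass
class RunConfig:
    """File-driven run configuration (YAML), mirroring the CLI options."""

    traits: str | None = None
    trees: str | None = None
    covariance_csvs: list[str] = field(default_factory=list)
    out_dir: str = "."
    seed: int = 0
    cri_level: float = 0.90
    lambda_mode: str | float = "estimate"  # "estimate" or a fixed value in [0, 1]
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def build_priors(self) -> Priors:
        return Priors(**self.priors)

    def build_mcmc(self) -> McmcConfig:
        return McmcConfig(seed=self.seed, cri_level=self.cri_level, **self.mcmc)

    def validate_paths(self) -> None:
        for p in [self.traits, self.trees, *self.covariance_csvs]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
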