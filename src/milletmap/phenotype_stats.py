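"""Multi-environment phenotype datasets, variance components, heritability.

The trial design is three locations × two years × replicates.  Analysis
works on twelve line-level datasets per trait: the six environment means
(Del-14, Del-15, Jod-14, Jod-15, DW-14, DW-15), three location means
(Del-M, Jod-M, DW-M), two year means (Y14-M, Y15-M) and the grand mean
(GM).  Pooled datasets are unweighted means of their constituent
environment datasets.

Variance components come from the balanced two-way ANOVA expected mean
squares (genotype, environment, G×E, residual), method of moments:

    σe²  = MS_error
    σGE² = (MS_GE − MS_error) / r
    σG²  = (MS_G − MS_GE) / (n·r)

with negative estimates clamped to zero, and broad-sense heritability

    H² = σG² / (σG² + σe²/r)                   (single environment)
    H² = σG² / (σG² + σGE²/n + σe²/(n·r))      (across n environments)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .panel_io import LOCATIONS, YEARS, PhenotypeTable

_LOC_SHORT = {"Delhi": "Del", "Jodhpur": "Jod", "Dharwad": "DW"}

ENVIRONMENT_DATASETS = tuple(
    f"{_LOC_SHORT[loc]}-{str(yr)[2:]}" for loc in LOCATIONS for yr in YEARS
)
POOLED_DATASETS = ("Del-M", "Jod-M", "DW-M", "Y14-M", "Y15-M", "GM")
ALL_DATASETS = ENVIRONMENT_DATASETS + POOLED_DATASETS

_POOL_MEMBERS = {
    "Del-M": ("Del-14", "Del-15"),
    "Jod-M": ("Jod-14", "Jod-15"),
    "DW-M": ("DW-14", "DW-15"),
    "Y14-M": ("Del-14", "Jod-14", "DW-14"),
    "Y15-M": ("Del-15", "Jod-15", "DW-15"),
    "GM": ENVIRONMENT_DATASETS,
}


@dataclass
class DatasetCollection:
    """Named line-level trait-mean vectors (pandas Series keyed by line)."""

    trait: str
    datasets: dict

    def __getitem__(self, name: str) -> pd.Series:
        return self.datasets[name]

    def names(self) -> list[str]:
        return list(self.datasets)


@dataclass
class VarianceComponents:
    sigma_G2: float
    sigma_GE2: float
    sigma_e2: float
    r: int
    n: int


def build_datasets(pheno: PhenotypeTable, trait: str) -> DatasetCollection:
    """Assemble the twelve per-trait analysis datasets.

    Environment datasets are per-line replicate means; pooled datasets are
    unweighted means of their member environments.  A line missing an entire
    environment is excluded (with a warning) from pooled datasets that
    involve it.
    """
    df = pheno.data[pheno.data["trait"] == trait]
    if df.empty:
        raise AnalysisError(f"no records for trait {trait!r}")
    env = (
        df.groupby(["line", "location", "year"])["value"].mean().reset_index()
    )
    env["dataset"] = [
        f"{_LOC_SHORT[loc]}-{str(yr)[2:]}" for loc, yr in zip(env["location"], env["year"])
    ]
    datasets: dict[str, pd.Series] = {}
    for name in ENVIRONMENT_DATASETS:
        s = env.loc[env["dataset"] == name].set_index("line")["value"].sort_index()
        s.name = name
        datasets[name] = s
    for name, members in _POOL_MEMBERS.items():
        frame = pd.concat([datasets[m] for m in members], axis=1)
        incomplete = frame.index[frame.isna().any(axis=1)]
        if len(incomplete):
            warnings.warn(
                f"{len(incomplete)} lines missing an environment excluded "
                f"from pooled dataset {name}"
            )
        s = frame.dropna().mean(axis=1)
        s.name = name
        datasets[name] = s
    return DatasetCollection(trait=trait, datasets=datasets)


def combined_anova(pheno: PhenotypeTable, trait: str) -> VarianceComponents:
    """Balanced two-way (genotype × environment) ANOVA variance components.

    Environments are the location-year combinations.  Requires ≥ 2
    environments and ≥ 2 replicates (the residual is inestimable from a
    single replicate).
    """
    df = pheno.data[pheno.data["trait"] == trait].copy()
    if df.empty:
        raise AnalysisError(f"no records for trait {trait!r}")
    df["env"] = df["location"].astype(str) + ":" + df["year"].astype(str)
    n_env = df["env"].nunique()
    reps = df.groupby(["line", "env"])["value"].count()
    r = int(reps.min())
    if n_env < 2:
        raise AnalysisError("combined ANOVA needs >= 2 environments")
    if r < 2:
        raise AnalysisError("combined ANOVA needs >= 2 replicates per cell")
    if reps.nunique() != 1:
        warnings.warn("unbalanced replicate counts; using the minimum per cell")
    grand = df["value"].mean()
    g_means = df.groupby("line")["value"].mean()
    e_means = df.groupby("env")["value"].mean()
    ge_means = df.groupby(["line", "env"])["value"].mean()
    n_g = len(g_means)

    ss_g = r * n_env * ((g_means - grand) ** 2).sum()
    ss_ge = r * (
        (
            ge_means
            - g_means.reindex(ge_means.index.get_level_values(0)).to_numpy()
            - e_means.reindex(ge_means.index.get_level_values(1)).to_numpy()
            + grand
        )
        ** 2
    ).sum()
    cell = ge_means.reindex(
        pd.MultiIndex.from_frame(df[["line", "env"]])
    ).to_numpy()
    ss_err = ((df["value"].to_numpy() - cell) ** 2).sum()

    ms_g = ss_g / (n_g - 1)
    ms_ge = ss_ge / ((n_g - 1) * (n_env - 1))
    ms_err = ss_err / (n_g * n_env * (r - 1))

    sigma_e2 = float(ms_err)
    sigma_ge2 = float(max((ms_ge - ms_err) / r, 0.0))
    sigma_g2 = float(max((ms_g - ms_ge) / (n_env * r), 0.0))
    return VarianceComponents(sigma_g2, sigma_ge2, sigma_e2, r=r, n=n_env)


def single_environment_anova(
    pheno: PhenotypeTable, trait: str, location: str, year: int
) -> VarianceComponents:
    """One-way (genotype) ANOVA components within a single environment.

    σe² = MS_error and σG² = (MS_G − MS_error)/r; the G×E component is not
    estimable from one environment and is returned as 0.
    """
    df = pheno.data[
        (pheno.data["trait"] == trait)
        & (pheno.data["location"] == location)
        & (pheno.data["year"] == year)
    ]
    if df.empty:
        raise AnalysisError(f"no records for {trait} at {location}:{year}")
    reps = df.groupby("line")["value"].count()
    r = int(reps.min())
    if r < 2:
        raise AnalysisError("single-environment ANOVA needs >= 2 replicates")
    g_means = df.groupby("line")["value"].mean()
    grand = df["value"].mean()
    n_g = len(g_means)
    ss_g = r * ((g_means - grand) ** 2).sum()
    within = df["value"].to_numpy() - g_means.reindex(df["line"]).to_numpy()
    ss_err = float((within**2).sum())
    ms_g = ss_g / (n_g - 1)
    ms_err = ss_err / (n_g * (r - 1))
    return VarianceComponents(
        float(max((ms_g - ms_err) / r, 0.0)), 0.0, float(ms_err), r=r, n=1
    )


def heritability(vc: VarianceComponents, mode: str = "multi") -> float:
    """Broad-sense heritability on an entry-mean basis (in [0, 1])."""
    if mode == "single":
        denom = vc.sigma_G2 + vc.sigma_e2 / vc.r
    elif mode == "multi":
        denom = vc.sigma_G2 + vc.sigma_GE2 / vc.n + vc.sigma_e2 / (vc.n * vc.r)
    else:
        raise AnalysisError(f"unknown heritability mode {mode!r}")
    if denom == 0:
        raise AnalysisError("all variance components are zero; H² undefined")
    return float(vc.sigma_G2 / denom)


def descriptive_table(pheno: PhenotypeTable, trait: str) -> pd.DataFrame:
    """Min / max / mean / SEm per dataset (layout of a trial summary table)."""
    coll = build_datasets(pheno, trait)
    rows = {}
    for name in ALL_DATASETS:
        s = coll[name]
        rows[name] = {
            "minimum": float(s.min()),
            "maximum": float(s.max()),
            "mean": float(s.mean()),
            "SEm": float(s.std(ddof=1) / np.sqrt(len(s))),
        }
    return pd.DataFrame(rows)


def structure_trait_correlation(
    line_ids: list, q: np.ndarray, dataset: pd.Series
) -> tuple[float, float]:
    """Regress a trait dataset on the K−1 leading Q columns; overall F-test.

    Returns (R², p).  K = 1 gives R² = 0, p = 1 by definition.
    """
    from scipy import stats

    q = np.asarray(q, float)
    common = [l for l in line_ids if l in dataset.index]
    idx = [line_ids.index(l) for l in common]
    y = dataset.loc[common].to_numpy(float)
    if q.shape[1] <= 1:
        return 0.0, 1.0
    X = np.column_stack([np.ones(len(common)), q[idx, : q.shape[1] - 1]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0, 1.0
    r2 = 1.0 - ss_res / ss_tot
    p_cov = X.shape[1] - 1
    df2 = len(y) - X.shape[1]
    if df2 <= 0 or ss_res <= 1e-12 * ss_tot:
        return r2, float(np.finfo(float).tiny)
    f = ((ss_tot - ss_res) / p_cov) / (ss_res / df2)
    return r2, float(stats.f.sf(f, p_cov, df2))
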