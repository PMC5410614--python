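"""Linkage disequilibrium and Q+K marker–trait association scans.

Models (per marker, per dataset):

    GLM:  y = Xa + Qb + e
    MLM:  y = Xa + Qb + Zu + e,   u ~ N(0, σu²·K),  e ~ N(0, σe²·I)

where X is the allele-dosage design of the tested marker (one 0/1/2 column
per allele class, reference class dropped), Q holds the leading K−1
admixture covariates, and K is the kinship matrix.  The MLM is fit
EMMA-style: REML on the marker-free null model via eigendecomposition of K
and one-dimensional optimization of the variance ratio, after which every
marker is tested on the whitened data with the null variance components
held fixed (P3D).  Marker p-values come from the partial F-test and marker
R² is SS_marker / SS_total (on the whitened scale for the MLM).

LD between multiallelic loci is the frequency-weighted composite r²

    r² = Σ_i Σ_j p_i q_j D_ij² / (p_i(1−p_i) q_j(1−q_j))

with D_ij estimated by pairing allele copies within individuals (no phase
needed); permutation p-values shuffle one locus's genotypes across lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .panel_io import GenotypePanel
from .population_structure import KinshipMatrix, QMatrix, SubpopAssignment

__all__ = [
    "MTARecord",
    "bonferroni_threshold",
    "ld_matrix",
    "glm_scan",
    "mlm_scan",
    "qq_data",
    "mta_frequency",
    "subpop_allele_anova",
]


@dataclass
class MTARecord:
    """One marker × trait × dataset association result."""

    marker_id: str
    trait: str
    dataset: str
    model: str
    p: float
    marker_R2: float
    allele_effects: list = field(default_factory=list)


def bonferroni_threshold(n_markers: int) -> tuple[float, float]:
    """The 1/n marker-count threshold with its −log10 to two decimals.

    This follows the common SSR association-mapping convention of taking
    p = 1/n (n = number of markers) as the multiplicity-corrected cutoff;
    a conventional α/n threshold is a caller-side one-liner.
    """
    if n_markers < 1:
        raise AnalysisError("n_markers must be >= 1")
    thr = 1.0 / n_markers
    return thr, round(-np.log10(thr), 2)


# ----------------------------------------------------------------------
# linkage disequilibrium
# ----------------------------------------------------------------------

def _pair_r2_from_joint(C: np.ndarray, total: float) -> float:
    """Composite r² from a joint allele-copy count table of one locus pair."""
    P = C / total
    p = P.sum(axis=1)
    q = P.sum(axis=0)
    if p.max() >= 1.0 - 1e-12 or q.max() >= 1.0 - 1e-12:
        return np.nan  # monomorphic side
    E = P - np.outer(p, q)
    W = np.outer(1.0 / (1.0 - p), 1.0 / (1.0 - q))
    return float((E**2 * W).sum())


def ld_matrix(
    panel: GenotypePanel, n_perm: int = 0, seed: int = 0
) -> pd.DataFrame:
    """All C(L,2) pairwise composite r² values with permutation p-values.

    Returns a DataFrame with columns ``marker1, marker2, r2, p,
    monomorphic``; pairs involving a monomorphic locus carry r² = 0 and are
    flagged.  With ``n_perm`` = 0 the p column is NaN.  Complete panels use
    a fully vectorized path; panels with missing calls fall back to a
    per-pair loop.
    """
    if panel.n_markers < 2:
        raise AnalysisError("need >= 2 loci for LD")
    if panel.missing_mask().any():
        return _ld_matrix_missing(panel, n_perm, seed)
    D, slices, alleles = panel.dosage()
    n, M = D.shape
    L = panel.n_markers
    Df = D.astype(float)
    starts = np.array([s.start for s in slices])
    f = Df.sum(axis=0) / (2.0 * n)
    mono = np.array([len(a) == 1 for a in alleles])
    winv = np.where(f < 1.0 - 1e-12, 1.0 / (1.0 - f), 0.0)

    def all_pair_r2(Dright: np.ndarray) -> np.ndarray:
        C = Df.T @ Dright / (4.0 * n)
        E = C - np.outer(f, f)
        Mt = (E * E) * np.outer(winv, winv)
        rows = np.add.reduceat(Mt, starts, axis=0)
        return np.add.reduceat(rows, starts, axis=1)

    r2 = all_pair_r2(Df)
    iu = np.triu_indices(L, k=1)
    obs = r2[iu]
    exceed = np.zeros_like(obs)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r2p = all_pair_r2(Df[perm])
            exceed += r2p[iu] >= obs - 1e-15
        pvals = (exceed + 1.0) / (n_perm + 1.0)
    else:
        pvals = np.full(obs.shape, np.nan)
    ids = panel.marker_ids
    mono_pair = mono[iu[0]] | mono[iu[1]]
    obs = np.where(mono_pair, 0.0, obs)
    pvals = np.where(mono_pair, np.nan, pvals)
    return pd.DataFrame(
        {
            "marker1": [ids[i] for i in iu[0]],
            "marker2": [ids[j] for j in iu[1]],
            "r2": obs,
            "p": pvals,
            "monomorphic": mono_pair,
        }
    )


def _ld_matrix_missing(panel: GenotypePanel, n_perm: int, seed: int) -> pd.DataFrame:
    D, slices, alleles = panel.dosage()
    ok = ~panel.missing_mask()
    rng = np.random.default_rng(seed)
    ids = panel.marker_ids
    rows = []
    for i in range(panel.n_markers):
        Di = D[:, slices[i]].astype(float)
        for j in range(i + 1, panel.n_markers):
            both = ok[:, i] & ok[:, j]
            m = int(both.sum())
            Dj = D[:, slices[j]].astype(float)
            mono = len(alleles[i]) == 1 or len(alleles[j]) == 1
            if m < 2 or mono:
                rows.append((ids[i], ids[j], 0.0, np.nan, True))
                continue
            A, B = Di[both], Dj[both]
            obs = _pair_r2_from_joint(A.T @ B, 4.0 * m)
            if np.isnan(obs):
                rows.append((ids[i], ids[j], 0.0, np.nan, True))
                continue
            if n_perm > 0:
                exceed = 0
                for _ in range(n_perm):
                    Bp = B[rng.permutation(m)]
                    r2p = _pair_r2_from_joint(A.T @ Bp, 4.0 * m)
                    if not np.isnan(r2p) and r2p >= obs - 1e-15:
                        exceed += 1
                p = (exceed + 1.0) / (n_perm + 1.0)
            else:
                p = np.nan
            rows.append((ids[i], ids[j], obs, p, False))
    return pd.DataFrame(rows, columns=["marker1", "marker2", "r2", "p", "monomorphic"])


# ----------------------------------------------------------------------
# marker designs
# ----------------------------------------------------------------------

def _marker_design(
    panel: GenotypePanel, j: int, row_idx: np.ndarray, min_class_size: int
):
    """Allele-dosage design for marker j restricted to ``row_idx`` lines.

    Rare alleles (fewer than ``min_class_size`` carriers) are merged into an
    'other' class; if 'other' itself stays rare it is folded into the
    reference.  The reference (largest-carrier) class is dropped.  Missing
    calls are mean-imputed so GLM and MLM see identical row sets.

    Returns (X, labels) or None if fewer than two eligible classes remain.
    """
    D, slices, alleles = panel.dosage()
    dos = D[np.ix_(row_idx, np.arange(slices[j].start, slices[j].stop))].astype(float)
    observed = ~panel.missing_mask()[row_idx, j]
    if observed.sum() < 2 * min_class_size:
        return None
    carriers = (dos[observed] > 0).sum(axis=0)
    common = carriers >= min_class_size
    labels = [str(int(a)) for a in alleles[j][common]]
    cols = [dos[:, k] for k in np.flatnonzero(common)]
    rare = ~common
    if rare.any():
        other = dos[:, rare].sum(axis=1)
        if (other[observed] > 0).sum() >= min_class_size:
            cols.append(other)
            labels.append("other")
    if len(cols) < 2:
        return None
    X = np.column_stack(cols)
    # mean-impute missing calls so every dataset line keeps its row
    if (~observed).any():
        X[~observed] = X[observed].mean(axis=0)
    # drop the largest class as reference
    ref = int(np.argmax((X[observed] > 0).sum(axis=0)))
    keep = [k for k in range(X.shape[1]) if k != ref]
    return X[:, keep], [labels[k] for k in keep]


def _partial_f(y, X0, X1, n_marker_cols) -> tuple[float, float, float, np.ndarray]:
    """(F, p, marker_R2, marker_betas) for nested OLS fits."""
    b0, rss0_, rank0, _ = np.linalg.lstsq(X0, y, rcond=None)
    b1, rss1_, rank1, _ = np.linalg.lstsq(X1, y, rcond=None)
    if rank1 < X1.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    rss0 = float(((y - X0 @ b0) ** 2).sum())
    rss1 = float(((y - X1 @ b1) ** 2).sum())
    df1 = n_marker_cols
    df2 = len(y) - X1.shape[1]
    if df2 <= 0:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    # total SS relative to the (possibly whitened) intercept-only model, so
    # the R2 definition is invariant to the kinship rotation and reduces to
    # the usual centered total SS in the OLS case
    b_int, *_ = np.linalg.lstsq(X0[:, :1], y, rcond=None)
    ss_tot = float(((y - X0[:, :1] @ b_int) ** 2).sum())
    r2 = (rss0 - rss1) / ss_tot if ss_tot > 0 else 0.0
    if rss1 <= 1e-300:
        return np.inf, np.finfo(float).tiny, max(r2, 0.0), b1[-df1:]
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(stats.f.sf(f, df1, df2))
    return f, max(p, np.finfo(float).tiny), max(r2, 0.0), b1[-df1:]


def _align(dataset: pd.Series, panel: GenotypePanel, Q: QMatrix | None):
    common = [l for l in panel.line_ids if l in dataset.index]
    if len(common) < 5:
        raise AnalysisError("too few lines shared between dataset and panel")
    row_idx = np.array([panel.line_ids.index(l) for l in common])
    y = dataset.loc[common].to_numpy(float)
    covs = [np.ones(len(common))]
    if Q is not None and Q.K > 1:
        qi = np.array([Q.line_ids.index(l) for l in common])
        covs.append(Q.q[qi, : Q.K - 1])  # drop last column: collinear with 1
    X0 = np.column_stack(covs)
    return common, row_idx, y, X0


def glm_scan(
    dataset: pd.Series,
    panel: GenotypePanel,
    Q: QMatrix | None,
    *,
    trait: str = "",
    dataset_name: str = "",
    min_class_size: int = 3,
) -> list[MTARecord]:
    """Per-marker fixed-effect scan: OLS of y on allele dosage + Q."""
    _, row_idx, y, X0 = _align(dataset, panel, Q)
    out = []
    for j, m in enumerate(panel.markers):
        des = _marker_design(panel, j, row_idx, min_class_size)
        if des is None:
            continue
        Xm, labels = des
        try:
            _, p, r2, betas = _partial_f(y, X0, np.column_stack([X0, Xm]), Xm.shape[1])
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"marker {m.marker_id}: {exc}; skipped")
            continue
        out.append(
            MTARecord(
                m.marker_id,
                trait,
                dataset_name,
                "GLM",
                p,
                min(r2, 1.0),
                [f"{lab}={b:+.4g}" for lab, b in zip(labels, betas)],
            )
        )
    return out


def _reml_variance_ratio(y, X, S) -> float:
    """REML estimate of λ = σu²/σe² on kinship-rotated data.

    ``y`` and ``X`` are already rotated by the kinship eigenvectors and
    ``S`` holds the eigenvalues.  Profiles out β and the scale, leaving a
    one-dimensional criterion in δ = σe²/σu² = 1/λ, optimized on a log grid
    with local refinement.
    """
    n, p = X.shape

    def neg_reml(log_delta: float) -> float:
        delta = 10.0**log_delta
        w = 1.0 / (S + delta)
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = y * sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = float(((yw - Xw @ beta) ** 2).sum())
        xtx = Xw.T @ Xw
        sign, logdet = np.linalg.slogdet(xtx)
        if sign <= 0 or rss <= 0:
            return np.inf
        return 0.5 * (
            (n - p) * np.log(rss) - np.sum(np.log(w)) + logdet
        )

    grid = np.linspace(-6, 6, 49)
    vals = [neg_reml(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    delta = 10.0 ** float(res.x)
    return 1.0 / delta


def mlm_scan(
    dataset: pd.Series,
    panel: GenotypePanel,
    Q: QMatrix | None,
    K: KinshipMatrix,
    *,
    trait: str = "",
    dataset_name: str = "",
    min_class_size: int = 3,
    variance_ratio: float | None = None,
) -> list[MTARecord]:
    """Q+K mixed-model scan, P3D style.

    Variance components are estimated once by REML on the marker-free null
    model and reused for every marker test on the whitened data.  Passing
    ``variance_ratio`` (λ = σu²/σe²) skips REML; λ = 0 reproduces the GLM
    exactly.
    """
    common, row_idx, y, X0 = _align(dataset, panel, Q)
    ki = np.array([K.line_ids.index(l) for l in common])
    Ksub = K.k[np.ix_(ki, ki)]
    S, U = np.linalg.eigh(Ksub)
    S = np.maximum(S, 0.0)
    yr = U.T @ y
    X0r = U.T @ X0
    if variance_ratio is None:
        lam = _reml_variance_ratio(yr, X0r, S)
    else:
        lam = variance_ratio
    if lam <= 1e-12:
        w = np.ones_like(S)  # no polygenic variance: identical to OLS
    else:
        w = 1.0 / (S + 1.0 / lam)
    sw = np.sqrt(w)
    yw = yr * sw
    X0w = X0r * sw[:, None]
    out = []
    for j, m in enumerate(panel.markers):
        des = _marker_design(panel, j, row_idx, min_class_size)
        if des is None:
            continue
        Xm, labels = des
        Xmw = (U.T @ Xm) * sw[:, None]
        try:
            _, p, r2, betas = _partial_f(
                yw, X0w, np.column_stack([X0w, Xmw]), Xm.shape[1]
            )
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"marker {m.marker_id}: {exc}; skipped")
            continue
        out.append(
            MTARecord(
                m.marker_id,
                trait,
                dataset_name,
                "MLM",
                p,
                min(r2, 1.0),
                [f"{lab}={b:+.4g}" for lab, b in zip(labels, betas)],
            )
        )
    return out


# ----------------------------------------------------------------------
# diagnostics and tallies
# ----------------------------------------------------------------------

def qq_data(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed p-value quantiles (both ascending).

    Expected quantiles are (i − 0.5)/m; pair with −log10 for plotting.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise AnalysisError("empty p-value list")
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return expected, np.sort(p)


def genomic_inflation(pvalues) -> float:
    """Median χ²(1) ratio λ_GC computed from two-sided p-values."""
    p = np.asarray(pvalues, float)
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1), df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def mta_frequency(records: list[MTARecord], threshold: float) -> pd.DataFrame:
    """Per marker × trait, how many datasets reached significance."""
    rows: dict[tuple, list] = {}
    for r in records:
        if r.p < threshold:
            rows.setdefault((r.marker_id, r.trait), []).append(r.dataset)
    out = [
        {
            "marker_id": mk,
            "trait": tr,
            "n_significant": len(ds),
            "datasets": ";".join(sorted(set(ds))),
        }
        for (mk, tr), ds in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["marker_id", "trait", "n_significant", "datasets"])


def subpop_allele_anova(
    panel: GenotypePanel,
    dataset: pd.Series,
    assignment: SubpopAssignment,
    marker_id: str,
    *,
    min_lines_per_class: int = 2,
) -> dict:
    """One-way ANOVA of trait on marker genotype class within each subpop.

    Genotype classes are the distinct unordered allele pairs; classes with
    fewer than ``min_lines_per_class`` lines are dropped and subpopulations
    left with fewer than two classes are skipped (returned as None).
    """
    try:
        j = panel.marker_ids.index(marker_id)
    except ValueError:
        raise AnalysisError(f"marker {marker_id!r} not in panel") from None
    results: dict[str, tuple | None] = {}
    for grp, lines in sorted(assignment.groups().items()):
        lines = [l for l in lines if l in dataset.index]
        classes: dict[tuple, list] = {}
        for l in lines:
            i = panel.line_ids.index(l)
            a, b = panel.calls[i, j]
            if a == -1:
                continue
            classes.setdefault((int(a), int(b)), []).append(float(dataset.loc[l]))
        groups = [v for v in classes.values() if len(v) >= min_lines_per_class]
        if len(groups) < 2:
            results[grp] = None
            continue
        if all(np.var(g) == 0 for g in groups) and len({np.mean(g) for g in groups}) == 1:
            results[grp] = (0.0, 1.0)
            continue
        f, p = stats.f_oneway(*groups)
        results[grp] = (float(f), float(p))
    return results
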