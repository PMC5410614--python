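"""Population structure: admixture, ΔK, clustering, kinship and AMOVA.

Admixture inference uses the classical mixture likelihood in which each
allele copy of line *i* at locus *l* is drawn from subpopulation *k* with
probability ``q_ik`` and then takes allele *a* with probability ``p_kla``.
The fit is maximum likelihood by EM with multiple random restarts; the
maximized log-likelihood of each restart is the per-run model score that the
Evanno ΔK second-difference statistic consumes for choosing K.

Also here: the Q ≥ 0.6 subpopulation assignment rule, Nei (1972) standard
genetic distance between lines, neighbor-joining trees, classical PCoA,
allele-sharing kinship, and a three-level AMOVA (among subpopulations /
among individuals within / within individuals) over allele copies with an
allele-mismatch distance.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio.tree import nj as _skbio_nj

from .errors import AnalysisError, ConfigError, ValidationError
from .panel_io import GenotypePanel

__all__ = [
    "QMatrix",
    "AdmixtureRun",
    "SubpopAssignment",
    "KinshipMatrix",
    "AmovaResult",
    "fit_admixture",
    "evanno_delta_k",
    "assign_subpopulations",
    "nei_distance",
    "nj_tree",
    "pcoa",
    "kinship",
    "amova",
    "align_q",
]


@dataclass
class QMatrix:
    """Lines × K admixture proportions; rows sum to 1."""

    line_ids: list
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.line_ids):
            raise ValidationError("Q shape does not match line ids")
        if np.any(self.q < -1e-12) or np.any(self.q > 1 + 1e-12):
            raise ValidationError("Q entries outside [0, 1]")
        if np.any(np.abs(self.q.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("Q rows must sum to 1")

    @property
    def K(self) -> int:
        return self.q.shape[1]


@dataclass
class AdmixtureRun:
    """One EM restart: its score and fitted parameters."""

    K: int
    restart: int
    loglik: float
    Q: QMatrix
    freqs: np.ndarray  # (K, n_loci, A_max), zero-padded
    n_iter: int
    converged: bool
    loglik_trace: list | None = None  # per-iteration scores, if tracked


@dataclass
class SubpopAssignment:
    """line_id -> subpopulation label ('A', 'B', ... or 'admixture')."""

    labels: dict

    def groups(self) -> dict:
        out: dict[str, list] = {}
        for line, lab in self.labels.items():
            out.setdefault(lab, []).append(line)
        return out


@dataclass
class KinshipMatrix:
    line_ids: list
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, float)
        n = len(self.line_ids)
        if self.k.shape != (n, n):
            raise ValidationError("kinship shape does not match line ids")
        if not np.allclose(self.k, self.k.T, atol=1e-10):
            raise ValidationError("kinship must be symmetric")


@dataclass
class AmovaResult:
    df_among: int
    df_among_individuals: int
    df_within: int
    ss_among: float
    ss_among_individuals: float
    ss_within: float
    var_among: float
    var_among_individuals: float
    var_within: float
    pct_among: float
    pct_among_individuals: float
    pct_within: float
    f_st: float
    p_value: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [
                    "Among sub-populations",
                    "Among individuals within sub-populations",
                    "Within individuals",
                    "Total",
                ],
                "df": [
                    self.df_among,
                    self.df_among_individuals,
                    self.df_within,
                    self.df_among + self.df_among_individuals + self.df_within,
                ],
                "SS": [
                    self.ss_among,
                    self.ss_among_individuals,
                    self.ss_within,
                    self.ss_among + self.ss_among_individuals + self.ss_within,
                ],
                "variance": [
                    self.var_among,
                    self.var_among_individuals,
                    self.var_within,
                    self.var_among + self.var_among_individuals + self.var_within,
                ],
                "percent": [
                    self.pct_among,
                    self.pct_among_individuals,
                    self.pct_within,
                    100.0,
                ],
            }
        )


# ----------------------------------------------------------------------
# admixture EM
# ----------------------------------------------------------------------

def _panel_encoding(panel: GenotypePanel):
    G, valid = panel.dosage_padded()
    n, L, A = G.shape
    Gf = G.reshape(n, L * A).astype(float)
    nz = np.nonzero(Gf)
    gnz = Gf[nz]
    copies = Gf.sum(axis=1)  # 2 × non-missing loci per line
    return Gf, nz, gnz, copies, valid, (L, A)


def _loglik(probs: np.ndarray, nz, gnz) -> float:
    pv = probs[nz]
    return float(np.dot(gnz, np.log(np.maximum(pv, 1e-300))))


def _pooled_freqs(panel: GenotypePanel) -> np.ndarray:
    G, valid = panel.dosage_padded()
    counts = G.sum(axis=0).astype(float)  # (L, A)
    tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        p = np.where(valid, counts / np.maximum(tot, 1.0), 0.0)
    return p


def fit_admixture(
    panel: GenotypePanel,
    K: int,
    restarts: int = 5,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    track_loglik: bool = False,
) -> list[AdmixtureRun]:
    """EM maximum-likelihood admixture fit, one run per random restart.

    Returns runs sorted by final log-likelihood (best first).  Within every
    run the log-likelihood sequence is non-decreasing (EM ascent).
    """
    if K < 1:
        raise ConfigError("K must be >= 1")
    if K > panel.n_lines:
        raise ConfigError(f"K={K} exceeds number of lines ({panel.n_lines})")
    Gf, nz, gnz, copies, valid, (L, A) = _panel_encoding(panel)
    n = panel.n_lines
    pooled = _pooled_freqs(panel)  # (L, A)
    validf = valid.reshape(1, L * A)

    if K == 1:
        p = pooled.reshape(1, L * A)
        probs = np.broadcast_to(p, (n, L * A))
        ll = _loglik(probs, nz, gnz)
        q = QMatrix(panel.line_ids, np.ones((n, 1)))
        run = AdmixtureRun(1, 0, ll, q, pooled[None, :, :].copy(), 0, True)
        return [run]

    rng_master = np.random.default_rng(np.random.SeedSequence([seed, K]))
    seeds = rng_master.spawn(restarts)
    runs: list[AdmixtureRun] = []
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        q = rng.dirichlet(np.full(K, 1.0 / K), size=n)
        q = np.maximum(q, 1e-6)
        q /= q.sum(axis=1, keepdims=True)
        # frequencies: pooled, perturbed per subpopulation
        noise = rng.uniform(0.5, 1.5, size=(K, L, A))
        p = np.where(valid, pooled[None] * noise, 0.0)
        p /= np.maximum(p.sum(axis=2, keepdims=True), 1e-300)
        p = p.reshape(K, L * A)

        ll_prev = -np.inf
        converged = False
        trace: list | None = [] if track_loglik else None
        w = np.zeros((n, L * A))
        for it in range(1, max_iter + 1):
            probs = q @ p
            ll = _loglik(probs, nz, gnz)
            if trace is not None:
                trace.append(ll)
            if ll - ll_prev < tol and it > 1:
                converged = True
                break
            ll_prev = ll
            w[nz] = gnz / np.maximum(probs[nz], 1e-300)
            # both updates use responsibilities from the same (q, p) pair,
            # which is what guarantees EM monotone ascent
            q_new = q * (w @ p.T)
            q_new /= np.maximum(q_new.sum(axis=1, keepdims=True), 1e-300)
            p_new = p * (q.T @ w)
            p_new = p_new.reshape(K, L, A)
            p_new /= np.maximum(p_new.sum(axis=2, keepdims=True), 1e-300)
            q, p = q_new, p_new.reshape(K, L * A)
        if not converged:
            ll = _loglik(q @ p, nz, gnz)
        runs.append(
            AdmixtureRun(
                K,
                r,
                ll,
                QMatrix(panel.line_ids, q / q.sum(axis=1, keepdims=True)),
                p.reshape(K, L, A).copy(),
                it,
                converged,
                trace,
            )
        )
    runs.sort(key=lambda run: -run.loglik)
    return runs


def evanno_delta_k(runs_by_k: dict[int, list[AdmixtureRun]]) -> pd.DataFrame:
    """Evanno second-difference statistic over per-K model scores.

    ``runs_by_k`` maps each K to its replicate runs (≥ 2 per K, ≥ 3
    consecutive K values).  ΔK is defined for interior K only:
    ``|mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))``; a zero
    replicate standard deviation yields +inf with a warning.
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise AnalysisError("need >= 3 consecutive K values for Evanno ΔK")
    for k in ks[1:]:  # K=1 has a closed-form fit; a single run is inherent
        if len(runs_by_k[k]) < 2:
            raise AnalysisError(f"need >= 2 replicate runs at K={k}")
    mean_l = {k: float(np.mean([r.loglik for r in runs_by_k[k]])) for k in ks}
    sd_l = {k: float(np.std([r.loglik for r in runs_by_k[k]], ddof=1)) if len(runs_by_k[k]) > 1 else 0.0 for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            num = abs(mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1])
            if sd_l[k] == 0.0:
                warnings.warn(f"sd of log-likelihood at K={k} is zero; ΔK = +inf")
                dk = np.inf
            else:
                dk = num / sd_l[k]
        rows.append({"K": k, "mean_loglik": mean_l[k], "sd_loglik": sd_l[k], "delta_K": dk})
    return pd.DataFrame(rows)


def best_k(delta_table: pd.DataFrame) -> int:
    """argmax ΔK over interior K (smallest K wins ties)."""
    interior = delta_table.dropna(subset=["delta_K"])
    if interior.empty:
        raise AnalysisError("no interior K values with a defined ΔK")
    return int(interior.loc[interior["delta_K"].idxmax(), "K"])


def align_q(q_est: np.ndarray, q_ref: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Resolve label switching: permute q_est columns to best match q_ref.

    Searches all column permutations (K ≤ ~8) and returns the permuted
    matrix and the permutation maximizing the trace of the cross-product.
    """
    K = q_est.shape[1]
    if q_ref.shape[1] != K:
        raise AnalysisError("Q matrices have different K")
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = float(np.sum(q_est[:, perm] * q_ref))
        if score > best_score:
            best_score, best_perm = score, perm
    return q_est[:, best_perm], best_perm


def assign_subpopulations(Q: QMatrix, threshold: float = 0.6) -> SubpopAssignment:
    """Label lines whose max membership reaches ``threshold`` (inclusive);
    the rest go to 'admixture'.  Groups are renamed A, B, C... by descending
    size; Q-row ties break toward the lowest subpopulation index.
    """
    if not 0.5 < threshold <= 1.0:
        raise ConfigError("threshold must be in (0.5, 1]")
    q = Q.q
    arg = q.argmax(axis=1)  # np.argmax takes the first (lowest) index on ties
    mx = q[np.arange(len(arg)), arg]
    assigned = mx >= threshold
    sizes = np.bincount(arg[assigned], minlength=Q.K)
    # descending size; stable tie-break by original column index
    order = np.lexsort((np.arange(Q.K), -sizes))
    name_of = {int(col): string.ascii_uppercase[rank] for rank, col in enumerate(order)}
    labels = {}
    for i, line in enumerate(Q.line_ids):
        labels[line] = name_of[int(arg[i])] if assigned[i] else "admixture"
    return SubpopAssignment(labels)


# ----------------------------------------------------------------------
# distances, trees, ordination
# ----------------------------------------------------------------------

def nei_distance(panel: GenotypePanel, cap: float = 10.0) -> pd.DataFrame:
    """Nei (1972) standard genetic distance between lines.

    Each line's profile at a locus is its allele-copy frequency vector
    (dosage / 2).  With J_xy, J_x, J_y the allele-product sums accumulated
    over loci, the identity is I = J_xy / sqrt(J_x J_y) and D = -ln I,
    capped at ``cap`` where I = 0.
    """
    if panel.n_lines < 2:
        raise AnalysisError("need >= 2 lines for a distance matrix")
    D, slices, _ = panel.dosage()
    X = D.astype(float) / 2.0  # (n, ΣA) per-locus frequency profiles
    J = X @ X.T
    diag = np.diag(J).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        I = J / np.sqrt(np.outer(diag, diag))
        dist = -np.log(np.maximum(I, np.exp(-cap)))
    dist = np.minimum(dist, cap)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    if np.all(dist == 0):
        warnings.warn("all pairwise Nei distances are zero (monomorphic panel?)")
    return pd.DataFrame(dist, index=panel.line_ids, columns=panel.line_ids)


def nj_tree(dist: pd.DataFrame):
    """Neighbor-joining tree (Saitou–Nei) from a distance matrix.

    Negative branch lengths are clamped to zero with the excess moved to the
    sister edge (scikit-bio's standard adjustment).  Returns a scikit-bio
    ``TreeNode``.
    """
    if dist.shape[0] < 3:
        raise AnalysisError("need >= 3 taxa for neighbor joining")
    dm = DistanceMatrix(dist.to_numpy(float), ids=[str(i) for i in dist.index])
    return _skbio_nj(dm, neg_as_zero=True)


def pcoa(dist: pd.DataFrame, n_axes: int = 2) -> tuple[pd.DataFrame, pd.Series]:
    """Classical (Gower) principal coordinate analysis.

    Negative eigenvalues are dropped with a warning; explained proportions
    are computed over the positive eigenvalues only.
    """
    dm = DistanceMatrix(dist.to_numpy(float), ids=[str(i) for i in dist.index])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio's own negative-eigenvalue warning
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    if (eig < -1e-8 * max(1.0, abs(eig).max())).any():
        warnings.warn("negative eigenvalues dropped from PCoA")
    pos = eig > 1e-12
    explained = pd.Series(eig[pos] / eig[pos].sum(), name="proportion_explained")
    coords = res.samples.iloc[:, : min(n_axes, int(pos.sum()))].copy()
    coords.index = list(dist.index)
    return coords, explained.iloc[:n_axes].reset_index(drop=True)


# ----------------------------------------------------------------------
# kinship
# ----------------------------------------------------------------------

def kinship(panel: GenotypePanel, eps: float = 1e-6) -> KinshipMatrix:
    """Allele-sharing kinship: mean over loci of (shared alleles)/2.

    Sharing between two diploid calls is sum_a min(dosage_a, dosage_b); loci
    missing in either line are skipped for that pair.  If the smallest
    eigenvalue is negative the matrix is shifted by +eps·I.
    """
    G, valid = panel.dosage_padded()
    n, L, A = G.shape
    miss = panel.missing_mask()  # (n, L)
    ok = (~miss).astype(float)
    pair_loci = ok @ ok.T  # loci callable in both lines
    shared = np.zeros((n, n))
    Gi = G.astype(np.int8)
    for j in range(L):
        d = Gi[:, j, :].astype(np.int16)  # (n, A)
        m = np.minimum(d[:, None, :], d[None, :, :]).sum(axis=2)
        shared += m
    with np.errstate(invalid="ignore", divide="ignore"):
        k = shared / (2.0 * np.maximum(pair_loci, 1.0))
    k = (k + k.T) / 2.0
    w = np.linalg.eigvalsh(k)
    if w.min() < 0:
        # shift just past the most negative eigenvalue (missing-data pairs
        # with differing locus sets can push it well below -eps)
        k = k + (eps - w.min()) * np.eye(n)
    return KinshipMatrix(panel.line_ids, k)


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------

def _ss_from_counts(counts: np.ndarray) -> float:
    """Sum over loci of (T^2 - sum m_a^2) / (2T) for one set of copies.

    ``counts`` is (L, A) allele-copy counts; with the allele-mismatch
    distance, the within-set sum of squares at a locus with copy counts m_a
    and total T is (T^2 - sum m_a^2) / (2T).
    """
    T = counts.sum(axis=1)
    good = T > 0
    m2 = (counts**2).sum(axis=1)
    return float((((T**2 - m2)[good]) / (2.0 * T[good])).sum())


def amova(
    panel: GenotypePanel,
    assignment: SubpopAssignment,
    n_perm: int = 999,
    seed: int = 0,
    include_admixture: bool = True,
) -> AmovaResult:
    """Three-level AMOVA over allele copies with a mismatch distance.

    Levels: among subpopulations, among individuals within subpopulations,
    within individuals.  The admixture group participates as a group of its
    own by default.  F_ST = Va / (Va + Vb + Vc); the p-value is the fraction
    of ``n_perm`` group-label permutations with F_ST at least the observed.
    """
    labels = [assignment.labels[l] for l in panel.line_ids]
    if not include_admixture:
        keep = [l for l, g in zip(panel.line_ids, labels) if g != "admixture"]
        panel = panel.subset_lines(keep)
        labels = [assignment.labels[l] for l in panel.line_ids]
    groups = sorted(set(labels))
    sizes = {g: labels.count(g) for g in groups}
    eligible = [g for g in groups if sizes[g] >= 2]
    single_group = len(groups) == 1
    if not single_group and len(eligible) < 2:
        raise AnalysisError("AMOVA needs >= 2 groups with >= 2 lines each")
    G, valid = panel.dosage_padded()
    n, L, A = G.shape
    g_idx = np.array([groups.index(g) for g in labels])
    ngroups = len(groups)

    Gf = G.astype(np.int64)
    total_counts = Gf.sum(axis=0)  # (L, A)
    ss_total = _ss_from_counts(total_counts)

    # within individuals: heterozygous call contributes 1/2 per locus
    het = (panel.calls[:, :, 0] != panel.calls[:, :, 1]) & (~panel.missing_mask())
    ss_wi = float(het.sum()) / 2.0

    def ss_within_groups(idx: np.ndarray) -> float:
        s = 0.0
        for g in range(ngroups):
            members = idx == g
            s += _ss_from_counts(Gf[members].sum(axis=0))
        return s

    ss_wg = ss_within_groups(g_idx)
    ss_ai = ss_wg - ss_wi
    ss_ag = ss_total - ss_wg

    df_ag = ngroups - 1
    df_ai = n - ngroups
    df_wi = n

    if single_group:
        # degenerate one-group case: no among-group level, F_ST = 0
        vc = ss_wi / df_wi
        vb = max((ss_ai / df_ai - vc) / 2.0, 0.0)
        tot = vb + vc
        return AmovaResult(
            df_among=0,
            df_among_individuals=df_ai,
            df_within=df_wi,
            ss_among=0.0,
            ss_among_individuals=ss_ai,
            ss_within=ss_wi,
            var_among=0.0,
            var_among_individuals=vb,
            var_within=vc,
            pct_among=0.0,
            pct_among_individuals=100 * vb / tot if tot else 0.0,
            pct_within=100 * vc / tot if tot else 0.0,
            f_st=0.0,
            p_value=1.0,
        )

    ms_wi = ss_wi / df_wi
    ms_ai = ss_ai / df_ai
    ms_ag = ss_ag / df_ag

    copies_per_group = np.array([2 * sizes[g] for g in groups], float)
    C = copies_per_group.sum()
    n_c = (C - (copies_per_group**2).sum() / C) / df_ag

    vc = ms_wi
    vb = (ms_ai - vc) / 2.0
    va = (ms_ag - vc - 2.0 * vb) / n_c
    va_raw = va  # unclamped: the permutation-test statistic

    clamped = False
    for name, v in (("Va", va), ("Vb", vb), ("Vc", vc)):
        if v < 0:
            clamped = True
    if clamped:
        warnings.warn("negative AMOVA variance component clamped to 0")
    va, vb, vc = max(va, 0.0), max(vb, 0.0), max(vc, 0.0)
    tot = va + vb + vc
    if tot == 0:
        pa = pb = pc = 0.0
        fst = 0.0
    else:
        pa, pb, pc = (100 * va / tot, 100 * vb / tot, 100 * vc / tot)
        fst = va / tot

    # permutation test: shuffle individuals among groups and compare the
    # unclamped among-group component (clamping would pile null p-values at
    # 1).  Only the among/within-group split changes under relabeling;
    # ss_total and ss_wi are invariant.
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(g_idx)
        ss_wg_p = ss_within_groups(perm)
        ms_ag_p = (ss_total - ss_wg_p) / df_ag
        ms_ai_p = (ss_wg_p - ss_wi) / df_ai
        vb_p = (ms_ai_p - vc) / 2.0
        va_p = (ms_ag_p - vc - 2.0 * vb_p) / n_c
        if va_p >= va_raw - 1e-12:
            exceed += 1
    p_value = (exceed + 1) / (n_perm + 1)

    return AmovaResult(
        df_among=df_ag,
        df_among_individuals=df_ai,
        df_within=df_wi,
        ss_among=ss_ag,
        ss_among_individuals=ss_ai,
        ss_within=ss_wi,
        var_among=va,
        var_among_individuals=vb,
        var_within=vc,
        pct_among=pa,
        pct_among_individuals=pb,
        pct_within=pc,
        f_st=fst,
        p_value=p_value,
    )
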