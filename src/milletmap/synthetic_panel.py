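"""Synthetic SSR panel and multi-environment phenotype generator.

The generator emulates a biofortification association panel: ~130
near-inbred lines genotyped at ~267 multiallelic SSR loci drawn from a
three-subpopulation admixture model, phenotyped for grain Fe and Zn (ppm)
at three locations over two years with three replicates.

Genotypes follow the correlated-allele-frequency (Balding–Nichols) model:
ancestral frequencies per locus are symmetric Dirichlet, each
subpopulation's frequencies are Dirichlet-drifted around them with
parameter ``drift_F``, line ancestry proportions are
Dirichlet(``admixture_alpha``), and each allele copy picks an ancestry from
the line's mixture before picking an allele — the same likelihood the
admixture EM fits, which keeps simulation and inference coherent.  A
``selfing_rate`` probability forces the second copy to duplicate the first,
producing the near-total homozygosity of selfed breeding lines.

Phenotypes are base mean + planted marker effects (favorable-copy count / 2
× effect, so a homozygous carrier shows the full effect) + a polygenic value
with covariance σG²·kinship + environment main effect + G×E deviate +
replicate residual.  Markers are simulated independently: linkage
disequilibrium arises from population structure only.

A :class:`SimTruth` record carries everything a recovery test needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel_io import (
    LOCATIONS,
    MISSING,
    TRAITS,
    YEARS,
    GenotypePanel,
    MarkerDef,
    PhenotypeTable,
)
from .population_structure import QMatrix, kinship


@dataclass(frozen=True)
class PlantedQTL:
    """A marker–trait effect planted in the simulation.

    ``effect`` is the ppm difference between a homozygous carrier of the
    favorable allele and a non-carrier; ``favorable_allele_index`` indexes
    the locus's allele list.
    """

    marker_index: int
    favorable_allele_index: int
    effect: float
    trait: str


@dataclass(frozen=True)
class TraitModel:
    """Per-trait base mean and variance components (ppm, ppm²)."""

    base_mean: float
    sigma_G2: float
    sigma_GE2: float
    sigma_e2: float


def _default_qtls() -> list[PlantedQTL]:
    # effects sized to explain roughly 10-18% of line-mean variance each
    return [
        PlantedQTL(10, 0, 10.0, "Fe"),
        PlantedQTL(40, 0, 9.0, "Fe"),
        PlantedQTL(70, 0, 8.0, "Fe"),
        PlantedQTL(100, 0, 8.0, "Zn"),
        PlantedQTL(130, 0, 7.0, "Zn"),
        PlantedQTL(160, 0, 6.0, "Zn"),
    ]


def _default_traits() -> dict:
    return {
        "Fe": TraitModel(base_mean=58.0, sigma_G2=90.0, sigma_GE2=80.0, sigma_e2=90.0),
        "Zn": TraitModel(base_mean=43.0, sigma_G2=40.0, sigma_GE2=35.0, sigma_e2=40.0),
    }


@dataclass
class SimConfig:
    n_lines: int = 130
    n_markers: int = 267
    K_true: int = 3
    drift_F: float = 0.15
    admixture_alpha: float = 0.2
    alleles_per_locus_range: tuple = (2, 5)
    selfing_rate: float = 0.9
    planted_qtls: list = field(default_factory=_default_qtls)
    traits: dict = field(default_factory=_default_traits)
    sigma_env2: float = 16.0
    n_locations: int = 3
    n_years: int = 2
    n_reps: int = 3
    missing_rate: float = 0.0
    planted_allele_freq: tuple = (0.2, 0.35)
    ancestral_dirichlet: float = 0.5
    plant_complementary_parents: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.drift_F < 1:
            raise ConfigError("drift_F must be in (0, 1)")
        if self.admixture_alpha < 0:
            raise ConfigError("admixture_alpha must be >= 0")
        if not 0 <= self.selfing_rate <= 1:
            raise ConfigError("selfing_rate must be in [0, 1]")
        for tm in self.traits.values():
            if min(tm.sigma_G2, tm.sigma_GE2, tm.sigma_e2) < 0:
                raise ConfigError("variance components must be nonnegative")
        if self.n_locations > len(LOCATIONS) or self.n_years > len(YEARS):
            raise ConfigError("n_locations/n_years exceed the supported design")
        seen: dict[str, set] = {}
        for qtl in self.planted_qtls:
            if not 0 <= qtl.marker_index < self.n_markers:
                raise ConfigError(
                    f"planted marker index {qtl.marker_index} out of range"
                )
            if qtl.trait not in self.traits:
                raise ConfigError(f"planted QTL for unknown trait {qtl.trait!r}")
            if qtl.marker_index in seen.setdefault(qtl.trait, set()):
                raise ConfigError("planted markers must be distinct per trait")
            seen[qtl.trait].add(qtl.marker_index)


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    q_true: QMatrix
    subpop_freqs: list  # per locus: (K_true, n_alleles) arrays
    allele_sizes: list  # per locus: bp sizes
    planted: list  # (marker_id, allele_bp, effect, trait)
    polygenic: dict  # trait -> per-line values
    env_effects: dict  # env name -> ppm deviation
    realized_components: dict  # trait -> {"sigma_G2": ..., ...}
    complementary_parents: tuple | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "line_ids": self.q_true.line_ids,
            "q_true": self.q_true.q.tolist(),
            "planted": [list(p) for p in self.planted],
            "polygenic": {t: list(map(float, v)) for t, v in self.polygenic.items()},
            "env_effects": self.env_effects,
            "realized_components": self.realized_components,
            "complementary_parents": self.complementary_parents,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _draw_locus_freqs(rng, n_alleles: int, cfg: SimConfig, planted_index: int | None):
    anc = rng.dirichlet(np.full(n_alleles, cfg.ancestral_dirichlet))
    if planted_index is not None:
        u = rng.uniform(*cfg.planted_allele_freq)
        others = np.delete(anc, planted_index)
        others = others / others.sum() * (1 - u)
        anc = np.insert(others, planted_index, u)
    anc = np.maximum(anc, 1e-3)
    anc /= anc.sum()
    scale = (1 - cfg.drift_F) / cfg.drift_F
    sub = np.stack([rng.dirichlet(anc * scale) for _ in range(cfg.K_true)])
    return anc, sub


def _draw_locus_genotypes(rng, q: np.ndarray, sub_freqs: np.ndarray, selfing: float):
    """(n, 2) allele indices for one locus under the admixture model."""
    n, K = q.shape
    cumq = np.cumsum(q, axis=1)
    z = (rng.random((n, 2, 1)) > cumq[:, None, :]).sum(axis=2)
    cump = np.cumsum(sub_freqs, axis=1)  # (K, A)
    a = (rng.random((n, 2, 1)) > cump[z]).sum(axis=2)
    selfed = rng.random(n) < selfing
    a[selfed, 1] = a[selfed, 0]
    return a


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, PhenotypeTable, SimTruth]:
    """Generate a genotype panel, phenotypes and ground truth.

    Deterministic under a fixed config (all randomness flows from
    ``config.seed``).  Loci whose realized allele count falls below 2 are
    redrawn (with fresh frequencies after repeated failures) so every locus
    in the returned panel is polymorphic.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, L, K = cfg.n_lines, cfg.n_markers, cfg.K_true
    lo, hi = cfg.alleles_per_locus_range

    line_ids = [f"line_{i + 1:03d}" for i in range(n)]
    markers = [MarkerDef(f"ssr_{j + 1:03d}") for j in range(L)]

    # ancestry proportions
    if cfg.admixture_alpha == 0:
        pop = rng.integers(0, K, size=n)
        q = np.zeros((n, K))
        q[np.arange(n), pop] = 1.0
    else:
        q = rng.dirichlet(np.full(K, cfg.admixture_alpha), size=n)

    planted_at = {qtl.marker_index: qtl for qtl in cfg.planted_qtls}

    allele_sizes: list[np.ndarray] = []
    sub_freqs: list[np.ndarray] = []
    calls = np.empty((n, L, 2), dtype=np.int32)
    geno_idx = np.empty((n, L, 2), dtype=np.int64)
    for j in range(L):
        n_alleles = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(80, 300))
        steps = rng.integers(2, 9, size=n_alleles - 1)
        sizes = start + np.concatenate([[0], np.cumsum(steps)])
        fav = planted_at[j].favorable_allele_index if j in planted_at else None
        if fav is not None and fav >= n_alleles:
            raise ConfigError(
                f"favorable allele index {fav} out of range at marker {j}"
            )
        anc, sub = _draw_locus_freqs(rng, n_alleles, cfg, fav)
        a = _draw_locus_genotypes(rng, q, sub, cfg.selfing_rate)
        # polymorphism guard: redraw until >= 2 realized alleles (and the
        # planted allele segregating at planted loci)
        for attempt in range(50):
            realized = np.unique(a)
            ok = len(realized) >= 2
            if ok and fav is not None:
                fav_count = (a == fav).sum()
                ok = 0 < fav_count < 2 * n
            if ok:
                break
            if attempt >= 10:
                anc, sub = _draw_locus_freqs(rng, n_alleles, cfg, fav)
            a = _draw_locus_genotypes(rng, q, sub, cfg.selfing_rate)
        allele_sizes.append(sizes)
        sub_freqs.append(sub)
        geno_idx[:, j, :] = a
        calls[:, j, :] = sizes[a]

    complementary: tuple | None = None
    if cfg.plant_complementary_parents:
        if n < 2 or not cfg.planted_qtls:
            raise ConfigError("complementary parents need >= 2 lines and planted QTLs")
        ordered = sorted(cfg.planted_qtls, key=lambda t: (t.trait, t.marker_index))
        half = (len(ordered) + 1) // 2
        for rank, qtl in enumerate(ordered):
            j, fav = qtl.marker_index, qtl.favorable_allele_index
            carrier, other = (0, 1) if rank < half else (1, 0)
            non_fav = 1 if fav == 0 else 0
            geno_idx[carrier, j, :] = fav
            geno_idx[other, j, :] = non_fav
            calls[carrier, j, :] = allele_sizes[j][fav]
            calls[other, j, :] = allele_sizes[j][non_fav]
        complementary = (line_ids[0], line_ids[1])

    if cfg.missing_rate > 0:
        miss = rng.random((n, L)) < cfg.missing_rate
        calls[miss] = MISSING

    panel = GenotypePanel(line_ids, markers, calls, missing_cap=1.0)

    # ---- phenotypes -------------------------------------------------
    # Polygenic covariance: allele-sharing kinship double-centered and
    # rescaled to unit mean diagonal.  Raw allele sharing has a large
    # constant baseline (unrelated lines share common alleles); centering
    # removes that shared component so the realized between-line genetic
    # variance equals sigma_G2 as configured.
    kin = kinship(panel)
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    B = C @ kin.k @ C
    B /= np.mean(np.diag(B))
    # eigen square root (robust to the tiny negative modes centering leaves)
    wB, UB = np.linalg.eigh(B)
    chol = UB * np.sqrt(np.maximum(wB, 0.0))
    locations = LOCATIONS[: cfg.n_locations]
    years = YEARS[: cfg.n_years]
    envs = [(loc, yr) for loc in locations for yr in years]
    env_eff = {f"{loc}:{yr}": float(rng.normal(0, np.sqrt(cfg.sigma_env2))) for loc, yr in envs}

    polygenic: dict[str, np.ndarray] = {}
    realized: dict[str, dict] = {}
    records = []
    for trait, tm in cfg.traits.items():
        g = chol @ rng.normal(size=n) * np.sqrt(tm.sigma_G2)
        polygenic[trait] = g
        qtl_val = np.zeros(n)
        for qtl in cfg.planted_qtls:
            if qtl.trait != trait:
                continue
            copies = (geno_idx[:, qtl.marker_index, :] == qtl.favorable_allele_index).sum(axis=1)
            # missing calls carry no planted effect
            copies = np.where(panel.missing_mask()[:, qtl.marker_index], 0, copies)
            qtl_val += copies / 2.0 * qtl.effect
        ge = rng.normal(0, np.sqrt(tm.sigma_GE2), size=(n, len(envs)))
        for e, (loc, yr) in enumerate(envs):
            base = tm.base_mean + env_eff[f"{loc}:{yr}"] + g + qtl_val + ge[:, e]
            for rep in range(1, cfg.n_reps + 1):
                vals = base + rng.normal(0, np.sqrt(tm.sigma_e2), size=n)
                vals = np.maximum(vals, 0.5)  # concentrations cannot go negative
                records.append(
                    pd.DataFrame(
                        {
                            "line": line_ids,
                            "location": loc,
                            "year": yr,
                            "replicate": rep,
                            "trait": trait,
                            "value": vals,
                        }
                    )
                )
        realized[trait] = {
            "sigma_G2": float(np.var(g + qtl_val, ddof=1)),
            "sigma_GE2": float(np.var(ge, ddof=1)),
            "sigma_e2": tm.sigma_e2,
        }

    pheno = PhenotypeTable(pd.concat(records, ignore_index=True))
    truth = SimTruth(
        q_true=QMatrix(line_ids, q),
        subpop_freqs=sub_freqs,
        allele_sizes=allele_sizes,
        planted=[
            (
                markers[qtl.marker_index].marker_id,
                int(allele_sizes[qtl.marker_index][qtl.favorable_allele_index]),
                qtl.effect,
                qtl.trait,
            )
            for qtl in cfg.planted_qtls
        ],
        polygenic=polygenic,
        env_effects=env_eff,
        realized_components=realized,
        complementary_parents=complementary,
    )
    return panel, pheno, truth


def config_from_dict(raw: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (e.g. parsed YAML)."""
    raw = dict(raw)
    if "planted_qtls" in raw:
        raw["planted_qtls"] = [PlantedQTL(**d) for d in raw["planted_qtls"]]
    if "traits" in raw:
        raw["traits"] = {t: TraitModel(**d) for t, d in raw["traits"].items()}
    for key in ("alleles_per_locus_range", "planted_allele_freq"):
        if key in raw:
            raw[key] = tuple(raw[key])
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**raw)
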