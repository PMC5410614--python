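"""Per-locus molecular diversity statistics for multiallelic SSR panels.

For allele frequencies :math:`p_1..p_A` at a locus (counted over allele
copies, two per non-missing diploid call):

* Nei gene diversity (expected heterozygosity) ``H = 1 - sum(p_i^2)``
* effective allele number ``n_e = 1 / sum(p_i^2)``
* polymorphism information content
  ``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``

Alleles with frequency below 5% are flagged as rare but never filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import GenotypePanel

RARE_FREQ = 0.05


@dataclass
class LocusSummary:
    marker_id: str
    n_a: int
    major_allele_freq: float
    n_e: float
    gene_diversity_H: float
    PIC: float
    rare_alleles: list = field(default_factory=list)


def _pic(p: np.ndarray) -> float:
    s2 = float(np.sum(p**2))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2**2 - s4)


def locus_stats(p: np.ndarray) -> tuple[float, float, float]:
    """(n_e, H, PIC) for one frequency vector (must sum to 1)."""
    p = np.asarray(p, float)
    s2 = float(np.sum(p**2))
    return 1.0 / s2, 1.0 - s2, _pic(p)


def allele_summary(panel: GenotypePanel) -> list[LocusSummary]:
    """One :class:`LocusSummary` per locus with ≥1 non-missing call.

    Loci with no callable copies are excluded with a warning (the panel
    validator normally rejects such loci already).
    """
    out: list[LocusSummary] = []
    D, slices, alleles = panel.dosage()
    for j, m in enumerate(panel.markers):
        counts = D[:, slices[j]].sum(axis=0).astype(float)
        total = counts.sum()
        if total == 0:
            warnings.warn(f"locus {m.marker_id!r} has no non-missing calls; excluded")
            continue
        p = counts / total
        n_e, H, pic = locus_stats(p)
        rare = [int(a) for a, f in zip(alleles[j], p) if f < RARE_FREQ]
        out.append(
            LocusSummary(
                marker_id=m.marker_id,
                n_a=len(p),
                major_allele_freq=float(p.max()),
                n_e=n_e,
                gene_diversity_H=H,
                PIC=pic,
                rare_alleles=rare,
            )
        )
    return out


def summary_table(summaries: list[LocusSummary]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "marker_id": s.marker_id,
                "n_a": s.n_a,
                "major_allele_freq": s.major_allele_freq,
                "n_e": s.n_e,
                "gene_diversity_H": s.gene_diversity_H,
                "PIC": s.PIC,
                "n_rare_alleles": len(s.rare_alleles),
            }
            for s in summaries
        ]
    )
    return df


def panel_means(summaries: list[LocusSummary]) -> dict[str, float]:
    """Panel-level means of the per-locus statistics.

    ``allele_deficit`` is (mean n_a − mean n_e)/mean n_a, the relative
    shortfall of effective versus observed allele number driven by
    low-frequency alleles.
    """
    df = summary_table(summaries)
    mean_na = float(df["n_a"].mean())
    mean_ne = float(df["n_e"].mean())
    return {
        "n_loci": float(len(df)),
        "total_alleles": float(df["n_a"].sum()),
        "mean_n_a": mean_na,
        "mean_n_e": mean_ne,
        "mean_major_allele_freq": float(df["major_allele_freq"].mean()),
        "mean_gene_diversity": float(df["gene_diversity_H"].mean()),
        "mean_PIC": float(df["PIC"].mean()),
        "allele_deficit": (mean_na - mean_ne) / mean_na,
    }
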