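"""Favorable-allele effects, carrier inventories and pyramiding crosses.

The phenotypic effect of allele *i* at a significant marker is

    a_i = (Σ_j x_ij) / n_i  −  (Σ_k N_k) / n_k

the mean trait value of the allele's carriers minus the mean over all lines
scored at the marker.  Alleles with a_i > 0 raise the trait; carriers of
the largest-effect alleles are the donors marker-assisted pyramiding wants
to combine.  Crosses are scored by the union of the two parents' favorable
allele sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .panel_io import GenotypePanel

__all__ = [
    "AlleleEffect",
    "CrossProposal",
    "allele_effects",
    "favorable_alleles",
    "genotype_allele_inventory",
    "propose_crosses",
]


@dataclass
class AlleleEffect:
    marker_id: str
    allele: int  # bp size
    trait: str
    dataset: str
    a_i: float
    n_i: int
    carriers: list = field(default_factory=list)  # ranked by trait value, best first


@dataclass
class CrossProposal:
    parent1: str
    parent2: str
    n_fe_alleles: int
    n_zn_alleles: int
    n_markers: int  # distinct markers covered across both traits
    score: int  # distinct (marker, allele, trait-agnostic) favorable pairs


def allele_effects(
    panel: GenotypePanel,
    dataset: pd.Series,
    markers: list[str],
    *,
    trait: str = "",
    dataset_name: str = "",
) -> list[AlleleEffect]:
    """Per-allele phenotypic effects for the given (significant) markers.

    The baseline is the mean over lines with a non-missing call at that
    marker, which keeps Σ n_i·a_i = 0 exactly on complete data where every
    line falls in one allele class.  Heterozygous lines contribute their
    full phenotype to each carried allele class.
    """
    out: list[AlleleEffect] = []
    lines = [l for l in panel.line_ids if l in dataset.index]
    if not lines:
        raise AnalysisError("no lines shared between dataset and panel")
    idx = {l: i for i, l in enumerate(panel.line_ids)}
    for mk in markers:
        try:
            j = panel.marker_ids.index(mk)
        except ValueError:
            raise AnalysisError(f"marker {mk!r} not in panel") from None
        scored = [
            l for l in lines if panel.calls[idx[l], j, 0] != -1
        ]
        if not scored:
            continue
        vals = dataset.loc[scored].to_numpy(float)
        pop_mean = float(vals.mean())
        carriers_of: dict[int, list] = {}
        for l in scored:
            a, b = (int(x) for x in panel.calls[idx[l], j])
            carriers_of.setdefault(a, []).append(l)
            if b != a:
                carriers_of.setdefault(b, []).append(l)
        for allele in sorted(carriers_of):
            carr = carriers_of[allele]
            cv = dataset.loc[carr].to_numpy(float)
            a_i = float(cv.mean() - pop_mean) if len(carriers_of) > 1 else 0.0
            ranked = [l for _, l in sorted(zip(-cv, carr))]
            out.append(
                AlleleEffect(
                    marker_id=mk,
                    allele=allele,
                    trait=trait,
                    dataset=dataset_name,
                    a_i=a_i,
                    n_i=len(carr),
                    carriers=ranked,
                )
            )
    return out


def favorable_alleles(
    effects: list[AlleleEffect],
    min_effect: float = 0.0,
    *,
    one_per_marker: bool = False,
    min_carriers: int = 1,
) -> list[AlleleEffect]:
    """Alleles with a_i above ``min_effect``, sorted by effect descending.

    The default keeps every positive-effect allele; raising ``min_effect``
    (e.g. to ~4 ppm) selects the large-effect subset used for cross
    planning.  Rare alleles show inflated apparent effects (their mean rides
    on a handful of lines), so cross planning should also set
    ``min_carriers`` (≥ 5 is a sensible floor on a ~130-line panel).  With
    ``one_per_marker`` only the superior (largest-effect) allele of each
    marker × trait survives, the pyramiding target a breeder would track
    with that marker.
    """
    keep = [e for e in effects if e.a_i > min_effect and e.n_i >= min_carriers]
    if one_per_marker:
        best: dict[tuple, AlleleEffect] = {}
        for e in keep:
            k = (e.trait, e.marker_id)
            if k not in best or e.a_i > best[k].a_i:
                best[k] = e
        keep = list(best.values())
    return sorted(keep, key=lambda e: -e.a_i)


def genotype_allele_inventory(
    panel: GenotypePanel, favorable: list[AlleleEffect]
) -> pd.DataFrame:
    """Per line, the favorable (marker, allele) pairs it carries.

    Returns a DataFrame indexed by line with one boolean column per
    favorable (trait, marker, allele) combination; column labels are
    ``trait|marker|allele``.
    """
    if not favorable:
        raise AnalysisError("favorable allele list is empty")
    cols = {}
    for e in favorable:
        key = f"{e.trait}|{e.marker_id}|{e.allele}"
        if key in cols:
            continue
        j = panel.marker_ids.index(e.marker_id)
        carried = (panel.calls[:, j, :] == e.allele).any(axis=1)
        cols[key] = carried
    return pd.DataFrame(cols, index=panel.line_ids)


def inventory_counts(inventory: pd.DataFrame) -> pd.DataFrame:
    """Distinct favorable alleles per line, per trait and combined."""
    traits = sorted({c.split("|")[0] for c in inventory.columns})
    out = pd.DataFrame(index=inventory.index)
    for t in traits:
        sub = [c for c in inventory.columns if c.startswith(f"{t}|")]
        out[t] = inventory[sub].sum(axis=1).astype(int)
    out["total"] = inventory.sum(axis=1).astype(int)
    return out


def propose_crosses(inventory: pd.DataFrame, top_n: int = 10) -> list[CrossProposal]:
    """Score all line pairs by the union of their favorable allele sets.

    The ranking score counts distinct favorable (trait, marker, allele)
    columns covered by either parent; ties break lexicographically on the
    parent-id pair.  Per-trait allele counts and the distinct-marker count
    are reported alongside.
    """
    lines = list(inventory.index)
    if len(lines) < 2:
        raise AnalysisError("need >= 2 lines to propose crosses")
    M = inventory.to_numpy(bool)
    cols = list(inventory.columns)
    fe_cols = np.array([c.startswith("Fe|") for c in cols])
    zn_cols = np.array([c.startswith("Zn|") for c in cols])
    markers = np.array([c.split("|")[1] for c in cols])
    proposals = []
    for i, j in combinations(range(len(lines)), 2):
        union = M[i] | M[j]
        pa, pb = sorted((str(lines[i]), str(lines[j])))
        proposals.append(
            CrossProposal(
                parent1=pa,
                parent2=pb,
                n_fe_alleles=int(union[fe_cols].sum()),
                n_zn_alleles=int(union[zn_cols].sum()),
                n_markers=len(set(markers[union])),
                score=int(union.sum()),
            )
        )
    proposals.sort(key=lambda c: (-c.score, c.parent1, c.parent2))
    return proposals[:top_n]
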