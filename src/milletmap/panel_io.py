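"""Readers, writers and core containers for SSR panel artifacts.

The central object is :class:`GenotypePanel`: a set of inbred-leaning lines
scored at multiallelic SSR loci, each call an *unordered* pair of amplicon
sizes in base pairs.  Phenotypes are long-format multi-environment records of
grain micronutrient concentration (ppm).  Everything downstream — diversity
statistics, admixture inference, mixed-model association scans and
favorable-allele mining — consumes these two containers.

On-disk dialects are deliberately plain: wide TSV for genotypes (cell
``"180/184"``, ``"180"`` for a homozygote, or a missing token), long CSV for
phenotypes, labeled CSV for Q and kinship matrices, TSV for result reports.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

MISSING = -1

LOCATIONS = ("Delhi", "Jodhpur", "Dharwad")
YEARS = (2014, 2015)
TRAITS = ("Fe", "Zn")

MARKER_CLASSES = ("genomic_ssr", "est_ssr", "genic")


@dataclass(frozen=True)
class MarkerDef:
    """Metadata for one SSR / genic marker.

    ``linkage_group`` and ``position_cM`` are optional map placements carried
    through as annotation only; a position is meaningful only when a linkage
    group is present.
    """

    marker_id: str
    linkage_group: str | None = None
    position_cM: float | None = None
    marker_class: str = "genomic_ssr"

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise ValidationError(
                f"marker {self.marker_id!r}: unknown marker_class {self.marker_class!r}"
            )
        if self.position_cM is not None:
            if self.linkage_group is None:
                raise ValidationError(
                    f"marker {self.marker_id!r}: position_cM given without linkage_group"
                )
            if self.position_cM < 0:
                raise ValidationError(
                    f"marker {self.marker_id!r}: negative position_cM"
                )


class GenotypePanel:
    """Lines × SSR loci diploid allele-size calls.

    Parameters
    ----------
    line_ids
        Ordered unique line names.
    markers
        Ordered :class:`MarkerDef` list, one per locus.
    calls
        ``(n_lines, n_markers, 2)`` integer array of allele sizes in bp;
        both slots ``-1`` for a missing call.  Pairs are unordered and are
        stored sorted.
    """

    def __init__(
        self,
        line_ids: Sequence[str],
        markers: Sequence[MarkerDef],
        calls: np.ndarray,
        *,
        max_alleles: int = 8,
        missing_cap: float = 0.2,
        validate: bool = True,
    ) -> None:
        self.line_ids = list(line_ids)
        self.markers = list(markers)
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(self.line_ids), len(self.markers), 2):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.line_ids)}, {len(self.markers)}, 2)"
            )
        self.calls = np.sort(calls, axis=2)
        # a call is missing iff both slots are MISSING; forbid half-missing
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValidationError(
                f"half-missing call at line {self.line_ids[i]!r}, "
                f"marker {self.markers[j].marker_id!r}"
            )
        self._cache: dict[str, object] = {}
        if validate:
            self.validate(max_alleles=max_alleles, missing_cap=missing_cap)

    # -- basic shape ---------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def missing_mask(self) -> np.ndarray:
        """(n_lines, n_markers) boolean, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def validate(self, *, max_alleles: int = 8, missing_cap: float = 0.2) -> None:
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicate line ids in panel")
        ids = self.marker_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate marker ids in panel")
        observed = self.calls[self.calls != MISSING]
        if observed.size and observed.min() <= 0:
            raise ValidationError("allele sizes must be positive integers")
        miss = self.missing_mask().mean(axis=0)
        bad = [ids[j] for j in np.flatnonzero(miss > missing_cap)]
        if bad:
            raise ValidationError(
                f"loci exceed missing-call cap of {missing_cap:.0%}: {bad}"
            )
        for j, alleles in enumerate(self.allele_values()):
            if len(alleles) == 0:
                raise ValidationError(f"locus {ids[j]!r} has no non-missing calls")
            if len(alleles) > max_alleles:
                raise ValidationError(
                    f"locus {ids[j]!r} has {len(alleles)} alleles "
                    f"(> max_alleles={max_alleles})"
                )

    # -- derived encodings --------------------------------------------
    def allele_values(self) -> list[np.ndarray]:
        """Per locus, the sorted distinct observed allele sizes."""
        key = "allele_values"
        if key not in self._cache:
            out = []
            for j in range(self.n_markers):
                col = self.calls[:, j, :].ravel()
                out.append(np.unique(col[col != MISSING]))
            self._cache[key] = out
        return self._cache[key]  # type: ignore[return-value]

    def dosage(self) -> tuple[np.ndarray, list[slice], list[np.ndarray]]:
        """Allele-copy dosage encoding.

        Returns ``(D, slices, alleles)`` where ``D`` is an
        ``(n_lines, total_alleles)`` array counting 0/1/2 copies of each
        observed allele (columns grouped by locus, missing calls all-zero),
        ``slices[j]`` selects locus *j*'s columns, and ``alleles[j]`` gives
        the bp size of each column.
        """
        key = "dosage"
        if key not in self._cache:
            alleles = self.allele_values()
            offsets = np.concatenate([[0], np.cumsum([len(a) for a in alleles])])
            D = np.zeros((self.n_lines, offsets[-1]), dtype=np.int8)
            for j, av in enumerate(alleles):
                idx = np.searchsorted(av, self.calls[:, j, :])
                ok = self.calls[:, j, 0] != MISSING
                for s in range(2):
                    rows = np.flatnonzero(ok)
                    np.add.at(D, (rows, offsets[j] + idx[rows, s]), 1)
            slices = [slice(offsets[j], offsets[j + 1]) for j in range(self.n_markers)]
            self._cache[key] = (D, slices, alleles)
        return self._cache[key]  # type: ignore[return-value]

    def dosage_padded(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded dosage tensor for vectorized likelihood work.

        Returns ``(G, valid)``: ``G`` is ``(n_lines, n_markers, A_max)``
        copy counts and ``valid`` an ``(n_markers, A_max)`` boolean mask of
        real allele columns.
        """
        key = "dosage_padded"
        if key not in self._cache:
            D, slices, alleles = self.dosage()
            amax = max(len(a) for a in alleles)
            G = np.zeros((self.n_lines, self.n_markers, amax), dtype=np.int8)
            valid = np.zeros((self.n_markers, amax), dtype=bool)
            for j, sl in enumerate(slices):
                G[:, j, : sl.stop - sl.start] = D[:, sl]
                valid[j, : sl.stop - sl.start] = True
            self._cache[key] = (G, valid)
        return self._cache[key]  # type: ignore[return-value]

    def subset_lines(self, keep: Sequence[str]) -> "GenotypePanel":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = [pos[l] for l in keep]
        return GenotypePanel(list(keep), self.markers, self.calls[idx], validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.line_ids == other.line_ids
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PhenotypeTable:
    """Long-format multi-environment phenotype records.

    Wraps a DataFrame with columns ``line, location, year, replicate, trait,
    value`` (value in ppm).  The (line, location, year, replicate, trait) key
    is unique and values are positive.
    """

    data: pd.DataFrame

    REQUIRED = ("line", "location", "year", "replicate", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        df = self.data.loc[:, list(self.REQUIRED)].copy()
        df["year"] = df["year"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        if (df["value"] <= 0).any():
            bad = df.loc[df["value"] <= 0].iloc[0]
            raise ValidationError(
                f"non-positive trait value {bad['value']} for line {bad['line']!r}"
            )
        bad_trait = set(df["trait"]) - set(TRAITS)
        if bad_trait:
            raise ValidationError(f"unknown traits: {sorted(bad_trait)}")
        key = ["line", "location", "year", "replicate", "trait"]
        if df.duplicated(subset=key).any():
            dup = df.loc[df.duplicated(subset=key)].iloc[0]
            raise ValidationError(
                "duplicate phenotype record for "
                + "/".join(str(dup[k]) for k in key)
            )
        self.data = df.reset_index(drop=True)

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    def check_against_panel(self, panel: GenotypePanel) -> list[str]:
        """Return (and warn about) phenotyped lines absent from the panel."""
        extra = sorted(set(self.data["line"]) - set(panel.line_ids))
        if extra:
            warnings.warn(
                f"{len(extra)} phenotyped lines not present in genotype panel: "
                f"{extra[:5]}{'...' if len(extra) > 5 else ''}",
                stacklevel=2,
            )
        return extra

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        a = self.data.sort_values(list(self.REQUIRED[:5])).reset_index(drop=True)
        b = other.data.sort_values(list(self.REQUIRED[:5])).reset_index(drop=True)
        return a.equals(b)


# ----------------------------------------------------------------------
# genotype TSV
# ----------------------------------------------------------------------

def _parse_call(token: str, missing_token: str, line_id: str, marker_id: str) -> tuple[int, int]:
    token = token.strip()
    if token == missing_token or token == "":
        return (MISSING, MISSING)
    parts = token.split("/")
    if len(parts) == 1:
        parts = parts * 2  # homozygote shorthand
    if len(parts) != 2:
        raise ParseError(
            f"cannot parse call {token!r} at line {line_id!r}, marker {marker_id!r}"
        )
    try:
        a, b = (int(p) for p in parts)
    except ValueError as exc:
        raise ParseError(
            f"non-integer allele token {token!r} at line {line_id!r}, "
            f"marker {marker_id!r}"
        ) from exc
    return (a, b)


def read_genotypes(
    path: str | Path,
    *,
    missing_token: str = "NA",
    max_alleles: int = 8,
    missing_cap: float = 0.2,
    marker_map: Sequence[MarkerDef] | None = None,
) -> GenotypePanel:
    """Read a wide genotype TSV (first column line id, one column per marker)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a line-id column plus marker columns")
    line_col = df.columns[0]
    line_ids = df[line_col].tolist()
    if len(set(line_ids)) != len(line_ids):
        dup = pd.Series(line_ids)
        raise ValidationError(
            f"{path}: duplicate line ids {sorted(dup[dup.duplicated()].unique())}"
        )
    marker_ids = list(df.columns[1:])
    if marker_map is not None:
        by_id = {m.marker_id: m for m in marker_map}
        unknown = [m for m in marker_ids if m not in by_id]
        if unknown:
            raise ValidationError(f"{path}: markers absent from marker map: {unknown}")
        markers = [by_id[m] for m in marker_ids]
    else:
        markers = [MarkerDef(m) for m in marker_ids]
    calls = np.empty((len(line_ids), len(marker_ids), 2), dtype=np.int32)
    for j, mk in enumerate(marker_ids):
        col = df[mk].tolist()
        for i, tok in enumerate(col):
            calls[i, j] = _parse_call(tok, missing_token, line_ids[i], mk)
    return GenotypePanel(
        line_ids, markers, calls, max_alleles=max_alleles, missing_cap=missing_cap
    )


def write_genotypes(
    panel: GenotypePanel, path: str | Path, *, missing_token: str = "NA"
) -> Path:
    path = Path(path)
    rows = []
    for i, lid in enumerate(panel.line_ids):
        row = {"line": lid}
        for j, m in enumerate(panel.markers):
            a, b = panel.calls[i, j]
            if a == MISSING:
                row[m.marker_id] = missing_token
            elif a == b:
                row[m.marker_id] = str(a)
            else:
                row[m.marker_id] = f"{a}/{b}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ----------------------------------------------------------------------
# marker map CSV
# ----------------------------------------------------------------------

def read_marker_map(path: str | Path) -> list[MarkerDef]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"marker_id", "linkage_group", "position_cM", "class"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: marker map needs columns {sorted(need)}")
    out = []
    for _, r in df.iterrows():
        lg = r["linkage_group"] or None
        pos = float(r["position_cM"]) if r["position_cM"] != "" else None
        out.append(MarkerDef(r["marker_id"], lg, pos, r["class"] or "genomic_ssr"))
    if len({m.marker_id for m in out}) != len(out):
        raise ValidationError(f"{path}: duplicate marker ids in map")
    return out


def write_marker_map(markers: Iterable[MarkerDef], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "marker_id": m.marker_id,
                "linkage_group": m.linkage_group or "",
                "position_cM": "" if m.position_cM is None else m.position_cM,
                "class": m.marker_class,
            }
            for m in markers
        ]
    ).to_csv(path, index=False)
    return path


# ----------------------------------------------------------------------
# phenotype CSV
# ----------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, float_precision="round_trip")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    # %.17g guarantees binary round-trip of the float values
    pheno.data.to_csv(path, index=False, float_format="%.17g")
    return path


# ----------------------------------------------------------------------
# Q matrix / kinship CSV
# ----------------------------------------------------------------------

def write_q_matrix(line_ids: Sequence[str], q: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    q = np.asarray(q, float)
    cols = [f"q{k + 1}" for k in range(q.shape[1])]
    df = pd.DataFrame(q, columns=cols)
    df.insert(0, "line", list(line_ids))
    df.to_csv(path, index=False, float_format="%.8f")
    return path


def read_q_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    lines = df["line"].astype(str).tolist()
    q = df.drop(columns=["line"]).to_numpy(float)
    rs = q.sum(axis=1)
    if np.any(np.abs(rs - 1.0) > 1e-6):
        raise ValidationError(f"{path}: Q rows do not sum to 1")
    q /= rs[:, None]  # undo serialization rounding exactly
    return lines, q


def write_kinship(line_ids: Sequence[str], k: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.asarray(k, float), index=list(line_ids), columns=list(line_ids))
    df.to_csv(path, float_format="%.8f")
    return path


def read_kinship(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: kinship row/column labels differ")
    return list(df.index.astype(str)), df.to_numpy(float)


# ----------------------------------------------------------------------
# generic report TSV (lists of result dataclasses)
# ----------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def write_report(records: Sequence, path: str | Path, *, kind: type | None = None) -> Path:
    """Write a list of result dataclasses as a TSV with stable column order.

    An empty list needs ``kind`` (the dataclass type) to emit a header-only
    file.
    """
    path = Path(path)
    if not records and kind is None:
        raise ValidationError("empty record list requires an explicit kind")
    cls = kind if kind is not None else type(records[0])
    if not dataclasses.is_dataclass(cls):
        raise ValidationError(f"{cls!r} is not a dataclass record type")
    names = [f.name for f in dataclasses.fields(cls)]
    rows = []
    for r in records:
        row = {}
        for n in names:
            v = getattr(r, n)
            if isinstance(v, float):
                v = _FLOAT_FMT % v
            elif isinstance(v, (list, tuple)):
                v = ";".join(str(x) for x in v)
            row[n] = v
        rows.append(row)
    pd.DataFrame(rows, columns=names).to_csv(path, sep="\t", index=False)
    return path


def read_report(path: str | Path, kind: type) -> list:
    """Read back a report written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fields = dataclasses.fields(kind)
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in fields:
            raw = row[f.name]
            if f.type in ("float", float):
                kwargs[f.name] = float(raw)
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif "list" in str(f.type):
                kwargs[f.name] = raw.split(";") if raw else []
            else:
                kwargs[f.name] = raw
        out.append(kind(**kwargs))
    return out


def write_newick(tree, path: str | Path) -> Path:
    """Write a scikit-bio TreeNode in newick format."""
    path = Path(path)
    tree.write(str(path), format="newick")
    return path
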