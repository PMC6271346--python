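"""Fatty-acid profiles, isolate libraries and taxon ratio matrices.

The central objects are:

* :class:`FAProfile` — one entity's FA composition within one lipid
  fraction (seston sample, microbial isolate, zooplankton fraction);
* :class:`TaxonRatioMatrix` — a taxa × FA table of FA amounts expressed
  relative to palmitic acid (16:0 = 1), the mixing signatures consumed by
  the unmixing engine;
* :class:`ReferenceLibrary` — labelled isolate profiles used for generic
  identification by profile similarity.

All FA names are canonicalized through :mod:`plfatax.nomenclature` on the
way in; downstream code compares canonical names only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nomenclature import FattyAcidParseError, canonicalize

__all__ = [
    "LIPID_FRACTIONS",
    "REFERENCE_FA",
    "FAProfile",
    "TaxonRatioMatrix",
    "ReferenceLibrary",
    "read_profiles",
    "write_profiles",
    "normalize_to_reference",
    "build_ratio_matrix",
    "identify_isolate",
]

LIPID_FRACTIONS = ("PLFA", "neutral", "acetone_mobile", "free_fa", "phospholipid", "total")

#: Reference FA for ratio matrices (palmitic acid).
REFERENCE_FA = "16:0"

#: Reserved (non-FA) column names in profile tables.
RESERVED_COLUMNS = ("entity_id", "lipid_fraction", "taxon")


@dataclass
class FAProfile:
    """One entity's fatty-acid composition within one lipid fraction.

    ``values`` maps canonical FA names to nonnegative quantities, either
    weight % of summed FA or mass per volume.  ``meta`` carries free-form
    annotations (pond code, taxon, sampling date, total FA mass, ...).
    """

    entity_id: str
    values: dict[str, float]
    lipid_fraction: str = "total"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lipid_fraction not in LIPID_FRACTIONS:
            raise ValueError(
                f"unknown lipid fraction {self.lipid_fraction!r}; expected one of {LIPID_FRACTIONS}"
            )
        canon: dict[str, float] = {}
        for name, v in self.values.items():
            c = canonicalize(name)
            if c in canon:
                raise ValueError(f"duplicate fatty-acid entry {c!r} in profile {self.entity_id!r}")
            v = float(v)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"profile {self.entity_id!r}: quantity for {c!r} must be finite and >= 0, got {v!r}"
                )
            canon[c] = v
        self.values = canon

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))

    def get(self, fa: str) -> float:
        return self.values.get(canonicalize(fa), 0.0)

    def as_weight_pct(self) -> "FAProfile":
        """Rescale quantities to weight % of summed FA (sum = 100)."""
        tot = self.total
        if tot <= 0:
            raise ValueError(f"profile {self.entity_id!r} has zero total FA")
        return FAProfile(
            entity_id=self.entity_id,
            values={k: 100.0 * v / tot for k, v in self.values.items()},
            lipid_fraction=self.lipid_fraction,
            meta=dict(self.meta),
        )

    def check_weight_pct(self, tol: float = 0.5) -> None:
        """Assert the weight-% convention (values sum to 100 within *tol*)."""
        if abs(self.total - 100.0) > tol:
            raise ValueError(
                f"profile {self.entity_id!r}: weight % sums to {self.total:.3f}, not 100 ± {tol}"
            )


def normalize_to_reference(p: FAProfile, reference: str = REFERENCE_FA) -> dict[str, float]:
    """Express a profile as ratios to a reference FA (default 16:0 → 1).

    Idempotent on already-normalized profiles; raises ``ValueError`` when
    the reference is absent or zero.
    """
    ref = canonicalize(reference)
    denom = p.values.get(ref, 0.0)
    if denom <= 0:
        raise ValueError(
            f"profile {p.entity_id!r}: reference FA {ref!r} absent or zero; cannot form ratios"
        )
    return {k: v / denom for k, v in p.values.items()}


@dataclass
class TaxonRatioMatrix:
    """Taxa × FA matrix of amounts relative to 16:0 (= 1 in every taxon).

    ``data`` is a DataFrame with taxa as the index and canonical FA names
    as columns; absent FAs are structural zeros (0.0).  Construction
    renormalizes every row by its 16:0 entry, so the reference column is
    exactly 1 afterwards.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.columns = [canonicalize(c) for c in df.columns]
        if len(set(df.columns)) != len(df.columns):
            raise ValueError("duplicate fatty-acid columns in ratio matrix")
        df = df.astype(float).fillna(0.0)
        if (df.to_numpy() < 0).any():
            raise ValueError("ratio matrix contains negative entries")
        if REFERENCE_FA not in df.columns:
            raise ValueError(f"ratio matrix lacks the reference column {REFERENCE_FA!r}")
        ref = df[REFERENCE_FA].to_numpy()
        if (ref <= 0).any():
            bad = [t for t, v in zip(df.index, ref) if v <= 0]
            raise ValueError(f"taxa with zero 16:0 reference entry: {bad}")
        df = df.div(df[REFERENCE_FA], axis=0)
        df[REFERENCE_FA] = 1.0  # exact
        df.index.name = None
        df.columns.name = None
        self.data = df

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def fas(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def restrict(self, taxa: Sequence[str]) -> "TaxonRatioMatrix":
        missing = [t for t in taxa if t not in self.data.index]
        if missing:
            raise KeyError(f"unknown taxa {missing}; available: {self.taxa}")
        return TaxonRatioMatrix(self.data.loc[list(taxa)].copy(), provenance=self.provenance)

    def to_csv(self, path: str | Path) -> None:
        """Write in the conventional layout: FA as rows, taxa as columns."""
        out = self.data.T.copy().replace(0.0, np.nan)
        out.index = out.index.copy()
        out.index.name = "fatty_acid"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "TaxonRatioMatrix":
        """Read a ratio matrix laid out with FA rows and taxon columns.

        Empty cells are structural zeros (FA absent from that taxon).
        """
        df = pd.read_csv(path, index_col=0)
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed numeric cell in ratio matrix {path}: {exc}") from exc
        return cls(df.T.fillna(0.0), provenance=provenance or str(path))


@dataclass
class ReferenceLibrary:
    """Labelled isolate FA profiles for similarity-based identification."""

    entries: list[tuple[str, FAProfile]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference library must contain at least one entry")

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.entries]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_profiles(path: str | Path) -> list[FAProfile]:
    """Read FA profiles from a CSV/TSV table.

    The header carries FA names plus the reserved columns ``entity_id``
    (required), ``lipid_fraction`` and ``taxon`` (optional; ``taxon`` lands
    in ``meta``).  Missing cells are read as 0 (FA not detected).  Two
    header names resolving to the same canonical FA are rejected.
    """
    df = _read_table(path)
    if "entity_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'entity_id'")
    fa_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    canon = {}
    for c in fa_cols:
        try:
            cc = canonicalize(c)
        except FattyAcidParseError as exc:
            raise FattyAcidParseError(f"{path}: bad fatty-acid column {c!r}: {exc}") from exc
        if cc in canon:
            raise ValueError(f"{path}: duplicate fatty-acid columns {canon[cc]!r} and {c!r} (both {cc!r})")
        canon[cc] = c

    profiles: list[FAProfile] = []
    for _, row in df.iterrows():
        values = {}
        for cc, c in canon.items():
            v = row[c]
            if pd.isna(v):
                v = 0.0
            try:
                v = float(v)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed numeric cell {row[c]!r} for {c!r}, entity {row['entity_id']!r}"
                ) from exc
            values[cc] = v
        meta = {}
        if "taxon" in df.columns and not pd.isna(row["taxon"]):
            meta["taxon"] = str(row["taxon"])
        fraction = "total"
        if "lipid_fraction" in df.columns and not pd.isna(row["lipid_fraction"]):
            fraction = str(row["lipid_fraction"])
        profiles.append(
            FAProfile(entity_id=str(row["entity_id"]), values=values, lipid_fraction=fraction, meta=meta)
        )
    return profiles


def write_profiles(profiles: Sequence[FAProfile], path: str | Path) -> None:
    """Write profiles to CSV/TSV (union of FAs as columns, absent = 0)."""
    fas: list[str] = []
    for p in profiles:
        for fa in p.values:
            if fa not in fas:
                fas.append(fa)
    rows = []
    for p in profiles:
        row: dict[str, object] = {"entity_id": p.entity_id, "lipid_fraction": p.lipid_fraction}
        if "taxon" in p.meta:
            row["taxon"] = p.meta["taxon"]
        row.update({fa: p.values.get(fa, 0.0) for fa in fas})
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def build_ratio_matrix(
    isolates: Sequence[tuple[str, FAProfile]],
    min_mean_pct: float = 1.0,
    drop_single_species: bool = True,
) -> TaxonRatioMatrix:
    """Average isolate profiles per taxon into a 16:0-referenced ratio matrix.

    Each isolate profile is first rescaled to weight % (the construction is
    therefore invariant to per-isolate scaling) and normalized to its 16:0
    entry; taxon signatures are arithmetic means of those ratio vectors.
    Two filters mirror common chemotaxonomic practice:

    * FAs whose mean weight % is below ``min_mean_pct`` in *every* taxon
      are dropped (minor, unstable peaks);
    * FAs detected in only one taxon of the library are dropped when
      ``drop_single_species`` is set (no cross-taxon information).

    The reference FA 16:0 is always retained.  A taxon left with no FA
    other than 16:0 is an error.
    """
    if not isolates:
        raise ValueError("no isolates given")
    by_taxon: dict[str, list[FAProfile]] = {}
    for taxon, prof in isolates:
        by_taxon.setdefault(str(taxon), []).append(prof.as_weight_pct())

    taxa = list(by_taxon)
    fas: list[str] = []
    for profs in by_taxon.values():
        for p in profs:
            for fa in p.values:
                if fa not in fas:
                    fas.append(fa)

    # per-taxon mean weight % (for the low-abundance filter) and mean ratios
    mean_pct = pd.DataFrame(0.0, index=taxa, columns=fas)
    mean_ratio = pd.DataFrame(0.0, index=taxa, columns=fas)
    for taxon, profs in by_taxon.items():
        pct = pd.DataFrame([{fa: p.values.get(fa, 0.0) for fa in fas} for p in profs])
        mean_pct.loc[taxon] = pct.mean(axis=0)
        ratios = pd.DataFrame([normalize_to_reference(p) for p in profs]).fillna(0.0)
        mean_ratio.loc[taxon] = ratios.reindex(columns=fas, fill_value=0.0).mean(axis=0)

    keep = []
    for fa in fas:
        if fa == REFERENCE_FA:
            keep.append(fa)
            continue
        if (mean_pct[fa] < min_mean_pct).all():
            continue
        if drop_single_species and (mean_pct[fa] > 0).sum() <= 1:
            continue
        keep.append(fa)

    out = mean_ratio[keep]
    for taxon in taxa:
        row = out.loc[taxon].drop(REFERENCE_FA)
        if (row <= 0).all():
            raise ValueError(f"taxon {taxon!r} has no surviving FA other than {REFERENCE_FA}")
    return TaxonRatioMatrix(out, provenance="build_ratio_matrix")


def identify_isolate(
    p: FAProfile, lib: ReferenceLibrary, top_k: int = 5
) -> list[tuple[str, float]]:
    """Rank library taxa by similarity to a query profile.

    Similarity is ``1 / (1 + d)`` with ``d`` the Euclidean distance between
    weight-% vectors over the union of FAs (absent FA = 0), so identical
    profiles score 1.  Ties are broken by taxon label, lexicographically.
    """
    q = p.as_weight_pct()
    scored: list[tuple[str, float]] = []
    for taxon, entry in lib.entries:
        e = entry.as_weight_pct()
        fas = set(q.values) | set(e.values)
        d = math.sqrt(sum((q.values.get(fa, 0.0) - e.values.get(fa, 0.0)) ** 2 for fa in fas))
        scored.append((taxon, 1.0 / (1.0 + d)))
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return scored[: max(1, int(top_k))]
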