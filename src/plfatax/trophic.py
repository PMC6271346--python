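"""Trophic marker sums and retention ratios.

Quantifies the contribution of fungi, bacteria and autotrophs to a
biomarker profile by summing group-specific marker FAs, pools zooplankton
lipid fractions (neutral / acetone-mobile / free FA / phospholipid), and
measures selective retention of essential FAs (EPA 20:5ω3, DHA 22:6ω3)
in consumers relative to the seston they feed on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .datasets import data_path
from .nomenclature import FattyAcidDescriptor, canonicalize, classify, parse_fa_name
from .profiles import FAProfile

__all__ = [
    "GROUPS",
    "MarkerScheme",
    "TrophicComparison",
    "default_scheme",
    "marker_proportions",
    "combine_lipid_fractions",
    "retention_ratio",
    "EPA",
    "DHA",
]

GROUPS = ("fungi", "bacteria", "autotrophs")

EPA = "20:5ω3"
DHA = "22:6ω3"


def _match_name(rule_fa: FattyAcidDescriptor, d: FattyAcidDescriptor) -> bool:
    """Name rules ignore cis/trans when the rule itself leaves it open."""
    if rule_fa.geometry is None and d.n_double_bonds >= 1:
        d = FattyAcidDescriptor(
            n_carbons=d.n_carbons,
            n_double_bonds=d.n_double_bonds,
            omega_position=d.omega_position,
            geometry=None,
            branch=d.branch,
            methyl_position=d.methyl_position,
            hydroxyl_position=d.hydroxyl_position,
            cyclopropyl=d.cyclopropyl,
        )
    return rule_fa == d


@dataclass
class MarkerScheme:
    """Ordered FA → trophic-group assignment rules.

    Each rule is ``{"group": g, "fa": name}`` (exact structural match;
    geometry-free rule names match any geometry) or ``{"group": g,
    "tag": t}`` with ``t`` a :func:`~plfatax.nomenclature.classify` tag.
    Rules are evaluated in order and the first match wins, so any FA maps
    to at most one group.  The scheme serializes to YAML and is meant to
    be human-auditable.
    """

    rules: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rule in self.rules:
            g = rule.get("group")
            if g not in GROUPS:
                raise ValueError(f"rule {rule!r}: group must be one of {GROUPS}")
            if ("fa" in rule) == ("tag" in rule):
                raise ValueError(f"rule {rule!r}: exactly one of 'fa'/'tag' required")
            if "fa" in rule:
                parse_fa_name(rule["fa"])  # validate eagerly

    def assign(self, fa: str | FattyAcidDescriptor) -> str | None:
        """Group of a fatty acid, or ``None`` if it is not a marker."""
        d = parse_fa_name(fa) if isinstance(fa, str) else fa
        tags = classify(d)
        for rule in self.rules:
            if "fa" in rule:
                if _match_name(parse_fa_name(rule["fa"]), d):
                    return rule["group"]
            elif rule["tag"] in tags:
                return rule["group"]
        return None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"rules": self.rules}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerScheme":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict) or "rules" not in payload:
            raise ValueError(f"{path}: marker scheme must be a mapping with a 'rules' list")
        return cls(rules=list(payload["rules"]))


def default_scheme() -> MarkerScheme:
    """The packaged fungi/bacteria/autotroph marker scheme."""
    from importlib import resources

    with resources.as_file(data_path("marker_scheme.yaml")) as p:
        return MarkerScheme.from_yaml(p)


def marker_proportions(
    p: FAProfile, scheme: MarkerScheme | None = None, relative: bool = True
) -> dict[str, float]:
    """Group proportions from summed marker FAs.

    Sums the weight % of each group's marker FAs.  With ``relative=True``
    (the default) the three group sums are renormalized to 1 over marker
    FAs only; with ``relative=False`` they are returned as fractions of
    total FA (non-marker FAs included in the denominator).  Scale-invariant
    either way.
    """
    scheme = scheme or default_scheme()
    q = p.as_weight_pct()
    sums = {g: 0.0 for g in GROUPS}
    for fa, v in q.values.items():
        g = scheme.assign(fa)
        if g is not None:
            sums[g] += v
    marker_total = sum(sums.values())
    if marker_total <= 0:
        raise ValueError(f"profile {p.entity_id!r} contains no marker FA mass")
    denom = marker_total if relative else 100.0
    return {g: v / denom for g, v in sums.items()}


def combine_lipid_fractions(
    profiles: Sequence[FAProfile],
    which: Iterable[str],
    masses: Mapping[str, float] | None = None,
) -> FAProfile:
    """Mass-weighted pooled profile over selected lipid fractions.

    All profiles must come from one entity.  Per-fraction FA masses are
    taken from ``masses`` (fraction → total FA mass), falling back to the
    ``fa_mass`` meta key, then to equal weights.  The pooled profile is
    expressed in weight % over the union of FAs.
    """
    which = list(which)
    if not profiles:
        raise ValueError("no profiles given")
    entity_ids = {p.entity_id for p in profiles}
    if len(entity_ids) != 1:
        raise ValueError(f"profiles from multiple entities: {sorted(entity_ids)}")
    by_fraction = {p.lipid_fraction: p for p in profiles}
    missing = [f for f in which if f not in by_fraction]
    if missing:
        raise KeyError(f"entity {profiles[0].entity_id!r}: missing lipid fractions {missing}")

    pooled: dict[str, float] = {}
    for frac in which:
        p = by_fraction[frac].as_weight_pct()
        if masses is not None and frac in masses:
            m = float(masses[frac])
        else:
            m = float(p.meta.get("fa_mass", 1.0))
        if m < 0:
            raise ValueError(f"negative fraction mass for {frac!r}")
        for fa, v in p.values.items():
            pooled[fa] = pooled.get(fa, 0.0) + m * v / 100.0
    out = FAProfile(
        entity_id=profiles[0].entity_id,
        values=pooled,
        lipid_fraction="total",
        meta={"pooled_fractions": which},
    )
    return out.as_weight_pct()


def retention_ratio(
    consumer: FAProfile,
    seston: FAProfile,
    fa_set: Iterable[str] = (EPA, DHA),
) -> float:
    """Consumer-to-seston ratio of an FA set's share of total FA.

    The default set is the essential ω3 PUFAs EPA and DHA; a ratio above 1
    indicates selective retention by the consumer.  Zero seston content of
    the set is an explicit error, never infinity.
    """
    fas = [canonicalize(f) for f in fa_set]
    if not fas:
        raise ValueError("fa_set must be nonempty")
    c = consumer.as_weight_pct()
    s = seston.as_weight_pct()
    s_sum = sum(s.values.get(f, 0.0) for f in fas)
    if s_sum <= 0:
        raise ValueError(f"seston {seston.entity_id!r} has zero content of {fas}")
    c_sum = sum(c.values.get(f, 0.0) for f in fas)
    return c_sum / s_sum


@dataclass
class TrophicComparison:
    """Seston vs consumer marker proportions plus retention ratios."""

    seston_proportions: dict[str, float]
    consumer_proportions: dict[str, dict[str, float]]  # fraction-set label → group → fraction
    retention: dict[str, float]  # FA-set label → consumer/seston ratio


#: Conventional lipid-fraction combinations for consumer marker panels:
#: reserve lipids alone, reserve + glycolipids + free FA, and membrane
#: phospholipids.
FRACTION_SETS: dict[str, tuple[str, ...]] = {
    "neutral": ("neutral",),
    "neutral+acetone_mobile+free_fa": ("neutral", "acetone_mobile", "free_fa"),
    "phospholipid": ("phospholipid",),
}


def trophic_comparison(
    seston: FAProfile,
    consumer_profiles: Sequence[FAProfile],
    scheme: MarkerScheme | None = None,
    fraction_sets: Mapping[str, Sequence[str]] | None = None,
    retention_sets: Mapping[str, Sequence[str]] | None = None,
) -> TrophicComparison:
    """Full seston-vs-consumer comparison for one consumer entity."""
    scheme = scheme or default_scheme()
    fraction_sets = dict(fraction_sets or FRACTION_SETS)
    retention_sets = dict(retention_sets or {"EPA+DHA": (EPA, DHA)})
    available = {p.lipid_fraction for p in consumer_profiles}
    consumer_props: dict[str, dict[str, float]] = {}
    retention: dict[str, float] = {}
    for label, fracs in fraction_sets.items():
        if not set(fracs) <= available:
            continue
        pooled = combine_lipid_fractions(consumer_profiles, fracs)
        consumer_props[label] = marker_proportions(pooled, scheme)
        if label == "neutral":
            for rlabel, fa_set in retention_sets.items():
                retention[rlabel] = retention_ratio(pooled, seston, fa_set)
    return TrophicComparison(
        seston_proportions=marker_proportions(seston, scheme),
        consumer_proportions=consumer_props,
        retention=retention,
    )
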