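"""Fatty-acid shorthand nomenclature: parsing, canonical spelling, classification.

Gas-chromatography software, culture-collection reports and the ecological
literature spell the same fatty acid in many ways: ``18:1ω9c``, ``18:1w9c``,
``15:0 iso``, ``i-15:0``, ``*i*-15:0``, ``16:00`` (for 16:0), ``3-OH 10:0``,
``10-Me 16:0``, ``cy19:0`` …  This module reduces every dialect to a single
structured :class:`FattyAcidDescriptor` and a deterministic canonical
spelling, so that the rest of the package never compares name strings.

Shorthand conventions
---------------------
``C:D``
    ``C`` carbons in the acyl chain with ``D`` double bonds.
``ωN`` (or ``wN``)
    position of the first double bond counted from the methyl (ω) end;
    an optional ``c``/``t`` suffix gives cis/trans geometry.
``i-`` / ``a-`` (also ``iso``/``anteiso``, prefix or suffix)
    methyl branch on the penultimate / antepenultimate carbon, typical of
    Gram-positive bacteria.
``k-Me``
    mid-chain methyl branch at carbon *k* (e.g. actinomycete 10-Me 16:0).
``k-OH``
    hydroxyl substituent at carbon *k* (Gram-negative lipid A hydroxy acids).
``cy``
    cyclopropane ring (cy17:0, cy19:0); by convention written saturated.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

__all__ = [
    "FattyAcidDescriptor",
    "FattyAcidParseError",
    "parse_fa_name",
    "canonical_name",
    "classify",
]


class FattyAcidParseError(ValueError):
    """Raised when a fatty-acid name cannot be interpreted.

    The message always names the offending token; malformed input is never
    silently coerced.
    """


_BRANCHES = ("none", "iso", "anteiso", "methyl")


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """Structured description of one fatty acid.

    Parameters
    ----------
    n_carbons
        Length of the acyl chain (≥ 2).
    n_double_bonds
        Number of C=C double bonds (≥ 0).
    omega_position
        Position of the first double bond from the methyl end; only
        meaningful (and only allowed) when ``n_double_bonds >= 1``.  May be
        ``None`` for an unsaturated acid whose position was not reported.
    geometry
        ``"c"`` (cis), ``"t"`` (trans) or ``None`` (unspecified); only
        allowed when ``n_double_bonds >= 1``.  An acid with unspecified
        geometry compares unequal to its cis and trans variants.
    branch
        ``"none"``, ``"iso"``, ``"anteiso"`` or ``"methyl"``; a ``"methyl"``
        branch carries its carbon position in ``methyl_position``.
    methyl_position
        Carbon index of a mid-chain methyl branch (``branch == "methyl"``).
    hydroxyl_position
        Carbon index of a hydroxyl substituent, or ``None``.
    cyclopropyl
        Whether the chain carries a cyclopropane ring (implies saturation).
    """

    n_carbons: int
    n_double_bonds: int = 0
    omega_position: int | None = None
    geometry: str | None = None
    branch: str = "none"
    methyl_position: int | None = None
    hydroxyl_position: int | None = None
    cyclopropyl: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.n_carbons, int) or self.n_carbons < 2:
            raise ValueError(f"n_carbons must be an integer >= 2, got {self.n_carbons!r}")
        if not isinstance(self.n_double_bonds, int) or self.n_double_bonds < 0:
            raise ValueError(f"n_double_bonds must be an integer >= 0, got {self.n_double_bonds!r}")
        if self.n_double_bonds == 0:
            if self.omega_position is not None:
                raise ValueError("omega_position requires at least one double bond")
            if self.geometry is not None:
                raise ValueError("geometry requires at least one double bond")
        if self.geometry is not None and self.omega_position is None:
            raise ValueError("geometry requires an explicit omega_position")
        if self.omega_position is not None and not (
            1 <= self.omega_position <= self.n_carbons - 1
        ):
            raise ValueError(f"omega_position {self.omega_position} outside chain of {self.n_carbons} carbons")
        if self.geometry not in (None, "c", "t"):
            raise ValueError(f"geometry must be 'c', 't' or None, got {self.geometry!r}")
        if self.branch not in _BRANCHES:
            raise ValueError(f"branch must be one of {_BRANCHES}, got {self.branch!r}")
        if self.branch == "anteiso" and self.n_carbons < 5:
            raise ValueError("anteiso branching requires at least 5 carbons")
        if self.branch == "methyl":
            if self.methyl_position is None:
                raise ValueError("methyl branch requires methyl_position")
            if not (2 <= self.methyl_position <= self.n_carbons - 1):
                raise ValueError(f"methyl_position {self.methyl_position} outside chain interior")
        elif self.methyl_position is not None:
            raise ValueError("methyl_position given without branch='methyl'")
        if self.hydroxyl_position is not None and not (
            1 <= self.hydroxyl_position <= self.n_carbons
        ):
            raise ValueError(f"hydroxyl_position {self.hydroxyl_position} outside chain")
        if self.cyclopropyl and self.n_double_bonds != 0:
            raise ValueError("cyclopropyl fatty acids are written saturated (n_double_bonds = 0)")

    @property
    def canonical_name(self) -> str:
        return canonical_name(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


# token patterns; applied after Unicode/markup normalization
_CORE_RE = re.compile(r"^(\d+):(\d+)(?:w(\d+)(c|t)?)?$", re.IGNORECASE)
_OH_PREFIX_RE = re.compile(r"^(\d+)-OH\s+", re.IGNORECASE)
_ME_PREFIX_RE = re.compile(r"^(\d+)-Me(?:thyl)?\s+", re.IGNORECASE)
_BRANCH_PREFIX_RE = re.compile(r"^(anteiso|ante|iso|a|i)-", re.IGNORECASE)
_BRANCH_SUFFIX_RE = re.compile(r"\s+(anteiso|ante|iso|a|i)$", re.IGNORECASE)
_CY_PREFIX_RE = re.compile(r"^cy(?:clo)?-?", re.IGNORECASE)

_BRANCH_WORD = {"i": "iso", "iso": "iso", "a": "anteiso", "ante": "anteiso", "anteiso": "anteiso"}


def _normalize_text(name: str) -> str:
    s = unicodedata.normalize("NFKC", name)
    s = s.replace("*", "").replace("_", "")  # italics / markup markers
    s = s.replace("ω", "w").replace("Ω", "w")
    s = re.sub(r"\s+", " ", s).strip()
    return s


def parse_fa_name(name: str) -> FattyAcidDescriptor:
    """Parse a fatty-acid name in any supported dialect.

    Raises
    ------
    FattyAcidParseError
        If the name (or any token of it) is not a recognizable fatty acid.

    Examples
    --------
    >>> parse_fa_name("18:1ω9c")
    FattyAcidDescriptor(n_carbons=18, n_double_bonds=1, omega_position=9, geometry='c', ...)
    >>> parse_fa_name("15:0 iso") == parse_fa_name("i-15:0")
    True
    """
    if not isinstance(name, str) or not name.strip():
        raise FattyAcidParseError(f"empty or non-text fatty-acid name: {name!r}")
    s = _normalize_text(name)

    hydroxyl_position: int | None = None
    branch = "none"
    methyl_position: int | None = None
    cyclopropyl = False

    m = _OH_PREFIX_RE.match(s)
    if m:
        hydroxyl_position = int(m.group(1))
        s = s[m.end():]

    m = _ME_PREFIX_RE.match(s)
    if m:
        branch = "methyl"
        methyl_position = int(m.group(1))
        s = s[m.end():]

    m = _BRANCH_PREFIX_RE.match(s)
    if m:
        if branch != "none":
            raise FattyAcidParseError(f"conflicting branch tokens in {name!r}")
        branch = _BRANCH_WORD[m.group(1).lower()]
        s = s[m.end():]

    m = _BRANCH_SUFFIX_RE.search(s)
    if m:
        if branch != "none":
            raise FattyAcidParseError(f"conflicting branch tokens in {name!r}")
        branch = _BRANCH_WORD[m.group(1).lower()]
        s = s[: m.start()]

    m = _CY_PREFIX_RE.match(s)
    if m and m.end() > 0:
        cyclopropyl = True
        s = s[m.end():]

    core = _CORE_RE.match(s)
    if core is None:
        raise FattyAcidParseError(f"unparseable fatty-acid token {s!r} in name {name!r}")
    n_carbons = int(core.group(1))
    n_double_bonds = int(core.group(2))  # "16:00" reads as 16:0
    omega = int(core.group(3)) if core.group(3) else None
    geometry = core.group(4).lower() if core.group(4) else None

    if n_double_bonds == 0 and omega is not None:
        raise FattyAcidParseError(f"{name!r}: ω-position given for a saturated acid")

    try:
        return FattyAcidDescriptor(
            n_carbons=n_carbons,
            n_double_bonds=n_double_bonds,
            omega_position=omega,
            geometry=geometry,
            branch=branch,
            methyl_position=methyl_position,
            hydroxyl_position=hydroxyl_position,
            cyclopropyl=cyclopropyl,
        )
    except ValueError as exc:
        raise FattyAcidParseError(f"invalid fatty acid {name!r}: {exc}") from exc


def canonical_name(d: FattyAcidDescriptor) -> str:
    """Deterministic canonical spelling; ``parse_fa_name`` round-trips it.

    Canonical dialect choices: ``i-``/``a-`` prefixes for iso/anteiso,
    ``k-Me`` and ``k-OH`` prefixes, ``cy`` prefix, ``ω`` for the double-bond
    position, lowercase ``c``/``t`` geometry suffix.
    """
    core = f"{d.n_carbons}:{d.n_double_bonds}"
    if d.n_double_bonds >= 1 and d.omega_position is not None:
        core += f"ω{d.omega_position}"
        if d.geometry is not None:
            core += d.geometry
    if d.cyclopropyl:
        core = "cy" + core
    if d.branch == "iso":
        core = "i-" + core
    elif d.branch == "anteiso":
        core = "a-" + core
    prefix = ""
    if d.hydroxyl_position is not None:
        prefix += f"{d.hydroxyl_position}-OH "
    if d.branch == "methyl":
        prefix += f"{d.methyl_position}-Me "
    return prefix + core


def canonicalize(name: str) -> str:
    """Shorthand for ``canonical_name(parse_fa_name(name))``."""
    return canonical_name(parse_fa_name(name))


def classify(d: FattyAcidDescriptor) -> frozenset[str]:
    """Structural category tags of a fatty acid.

    Tags: ``SAFA`` (saturated), ``MUFA`` (one double bond), ``PUFA``
    (two or more), ``C16_PUFA``/``C18_PUFA`` (the autotroph marker
    classes), ``iso_anteiso``, ``hydroxy``, ``cyclopropyl``,
    ``methyl_branched`` (mid-chain methyl), ``short_chain_lt14``
    (fewer than 14 carbons).
    """
    tags: set[str] = set()
    if d.n_double_bonds == 0:
        tags.add("SAFA")
    elif d.n_double_bonds == 1:
        tags.add("MUFA")
    else:
        tags.add("PUFA")
        if d.n_carbons == 16:
            tags.add("C16_PUFA")
        elif d.n_carbons == 18:
            tags.add("C18_PUFA")
    if d.branch in ("iso", "anteiso"):
        tags.add("iso_anteiso")
    if d.branch == "methyl":
        tags.add("methyl_branched")
    if d.hydroxyl_position is not None:
        tags.add("hydroxy")
    if d.cyclopropyl:
        tags.add("cyclopropyl")
    if d.n_carbons < 14:
        tags.add("short_chain_lt14")
    return frozenset(tags)
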