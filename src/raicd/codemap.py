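"""ICD-10-CM code normalization and the parameter code map.

The RAI-ICD instrument defines nine diagnosis-code-based parameters
(unintentional weight loss, poor appetite, congestive heart failure,
shortness of breath, kidney failure, cancer, partial and total functional
dependence, cognitive decline).  Each parameter owns a set of ICD-10-CM code
patterns; a discharge record exhibits the parameter when at least one of its
diagnosis codes matches one of the patterns.  Malignant-neoplasm codes
(C00–C96) additionally carry a severity tier (severe / moderate / mild,
anchored on 5-year survival) used for cancer-definition model selection.

The map is data, not code: it is loaded from a structured YAML file so users
can substitute updated ICD-10-CM releases or institution-specific mappings.
The packaged default, ``codemap_synthetic_v1.yaml``, is a *synthetic
reconstruction* — a clinically plausible 323-code listing with the same
structure and size as the instrument's official code list, which is licensed
and not redistributed here.  A reduced demo map is shipped alongside it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import CodeMapError, InvalidCodeError

__all__ = [
    "CODE_PARAMETERS",
    "CANCER_TIERS",
    "CodePattern",
    "ParameterCodeMap",
    "ParameterHits",
    "normalize_code",
    "matches",
    "lookup_parameters",
    "load_code_map",
    "save_code_map",
    "default_code_map",
    "demo_code_map",
]

#: The nine code-based parameters, in canonical order.
CODE_PARAMETERS = (
    "weight_loss",
    "poor_appetite",
    "congestive_heart_failure",
    "shortness_of_breath",
    "kidney_failure",
    "cancer",
    "functional_status_partial",
    "functional_status_total",
    "cognitive_decline",
)

#: Cancer severity tiers, most severe first.
CANCER_TIERS = ("severe", "moderate", "mild")
_TIER_RANK = {t: i for i, t in enumerate(CANCER_TIERS)}

_CODE_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]{1,5}$")

#: Patterns at 3- or 4-character granularity denote code families and match
#: all descendants; fully specified codes (5+ characters) match exactly.
PREFIX_MAX_LEN = 4


def normalize_code(raw: str) -> str:
    """Normalize a raw ICD-10-CM code string.

    Uppercases, strips surrounding whitespace and removes the decimal point,
    e.g. ``"z51.5" -> "Z515"``.  Idempotent on its own output.

    Raises
    ------
    InvalidCodeError
        If the input is empty after trimming or does not conform to the
        ICD-10-CM shape (letter, digit, then 1–5 alphanumerics).
    """
    if raw is None:
        raise InvalidCodeError("ICD-10-CM code is missing (None)")
    code = str(raw).strip().upper().replace(".", "").replace(" ", "")
    if not code:
        raise InvalidCodeError(f"empty ICD-10-CM code: {raw!r}")
    if not _CODE_RE.match(code):
        raise InvalidCodeError(f"not a valid ICD-10-CM code: {raw!r} (normalized {code!r})")
    return code


@dataclass(frozen=True)
class CodePattern:
    """A normalized ICD-10-CM code pattern with exact-or-prefix semantics."""

    pattern: str
    prefix: bool = False

    @classmethod
    def from_string(cls, raw: str) -> "CodePattern":
        """Build a pattern from a raw code, inferring the match mode.

        Patterns of :data:`PREFIX_MAX_LEN` characters or fewer match as
        prefixes (ICD-10-CM is hierarchical, so a 3- or 4-character family
        covers every descendant); longer patterns match exactly.
        """
        code = normalize_code(raw)
        return cls(pattern=code, prefix=len(code) <= PREFIX_MAX_LEN)

    def matches(self, code: str) -> bool:
        if self.prefix:
            return code.startswith(self.pattern)
        return code == self.pattern


def matches(code: str, pattern: CodePattern) -> bool:
    """True iff ``code`` equals ``pattern`` or, in prefix mode, starts with it."""
    return pattern.matches(code)


def _in_cancer_block(pattern: str) -> bool:
    # C00–C96; ICD-10-CM interleaves alphanumeric categories (C4A, C7A, C7B)
    # which lexicographically sort inside the block.
    if not pattern.startswith("C") or len(pattern) < 3:
        return False
    cat = pattern[1:3]
    if cat[1].isalpha():
        return cat[0].isdigit() and int(cat[0]) <= 9
    return cat.isdigit() and int(cat) <= 96


@dataclass(frozen=True)
class ParameterHits:
    """Result of resolving a code list against a map."""

    parameters: frozenset[str]
    cancer_tier: str | None
    unmatched: tuple[str, ...] = ()

    def as_set(self) -> set[tuple[str, str | None]]:
        """The spec-level view: a set of (parameter, tier-or-None) hits."""
        return {
            (p, self.cancer_tier if p == "cancer" else None) for p in self.parameters
        }


@dataclass
class ParameterCodeMap:
    """Mapping from RAI parameters to ICD-10-CM code patterns.

    Parameters
    ----------
    entries
        parameter name -> sequence of :class:`CodePattern`.
    cancer_tiers
        cancer pattern string -> tier in :data:`CANCER_TIERS`.
    version
        Free-text version label, preserved on round-trip.
    """

    entries: dict[str, tuple[CodePattern, ...]]
    cancer_tiers: dict[str, str] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        for param, patterns in self.entries.items():
            if param not in CODE_PARAMETERS:
                raise CodeMapError(f"unknown parameter {param!r}")
            seen: set[str] = set()
            for pat in patterns:
                if pat.pattern in seen:
                    raise CodeMapError(
                        f"duplicate pattern {pat.pattern!r} within parameter {param!r}"
                    )
                seen.add(pat.pattern)
        for pat in self.entries.get("cancer", ()):
            if not _in_cancer_block(pat.pattern):
                raise CodeMapError(
                    f"cancer pattern {pat.pattern!r} outside the C00–C96 block"
                )
            tier = self.cancer_tiers.get(pat.pattern)
            if tier not in CANCER_TIERS:
                raise CodeMapError(
                    f"cancer pattern {pat.pattern!r} lacks a valid severity tier"
                )
        partial = {p.pattern for p in self.entries.get("functional_status_partial", ())}
        total = {p.pattern for p in self.entries.get("functional_status_total", ())}
        overlap = partial & total
        if overlap:
            raise CodeMapError(
                f"partial/total functional-status pattern sets overlap: {sorted(overlap)}"
            )

    @property
    def n_codes(self) -> int:
        """Total number of distinct code patterns across all parameters."""
        return len({p.pattern for pats in self.entries.values() for p in pats})

    def patterns(self, parameter: str) -> tuple[CodePattern, ...]:
        return self.entries.get(parameter, ())

    def tier_of(self, cancer_pattern: str) -> str:
        return self.cancer_tiers[cancer_pattern]

    # -- lookup ------------------------------------------------------------
    def build_index(self) -> "_MapIndex":
        return _MapIndex(self)


class _MapIndex:
    """Dictionary index over a map for O(1)-per-code lookups.

    Exact patterns are keyed by their full string; prefix patterns are keyed
    by the prefix, and a code is probed at every prefix length present in the
    map (in practice lengths 3–4).
    """

    def __init__(self, cmap: ParameterCodeMap) -> None:
        self.cmap = cmap
        self.exact: dict[str, list[tuple[str, str | None]]] = {}
        self.prefix: dict[str, list[tuple[str, str | None]]] = {}
        self.prefix_lengths: tuple[int, ...] = ()
        lengths: set[int] = set()
        for param, patterns in cmap.entries.items():
            for pat in patterns:
                tier = cmap.cancer_tiers.get(pat.pattern) if param == "cancer" else None
                target = self.prefix if pat.prefix else self.exact
                target.setdefault(pat.pattern, []).append((param, tier))
                if pat.prefix:
                    lengths.add(len(pat.pattern))
        self.prefix_lengths = tuple(sorted(lengths))

    def hits_for_code(self, code: str) -> list[tuple[str, str | None]]:
        out = list(self.exact.get(code, ()))
        for ln in self.prefix_lengths:
            if ln <= len(code):
                out.extend(self.prefix.get(code[:ln], ()))
        return out


def lookup_parameters(
    codes: Iterable[str], cmap: ParameterCodeMap, index: _MapIndex | None = None
) -> ParameterHits:
    """Resolve a list of normalized codes to the set of present parameters.

    A parameter is present when at least one of its patterns matches any
    code.  A cancer hit carries the most severe tier among matched cancer
    codes (severe > moderate > mild).  Codes matching nothing are ignored
    and returned in a diagnostics tally; the result is invariant to the
    order and multiplicity of the code list.
    """
    idx = index if index is not None else cmap.build_index()
    present: set[str] = set()
    best_tier: str | None = None
    unmatched: list[str] = []
    for code in codes:
        hits = idx.hits_for_code(code)
        if not hits:
            unmatched.append(code)
            continue
        for param, tier in hits:
            present.add(param)
            if param == "cancer" and tier is not None:
                if best_tier is None or _TIER_RANK[tier] < _TIER_RANK[best_tier]:
                    best_tier = tier
    return ParameterHits(
        parameters=frozenset(present),
        cancer_tier=best_tier,
        unmatched=tuple(unmatched),
    )


# -- persistence -----------------------------------------------------------

def _map_to_dict(cmap: ParameterCodeMap) -> dict:
    doc: dict = {"version": cmap.version, "parameters": {}}
    for param in CODE_PARAMETERS:
        if param == "cancer" or param not in cmap.entries:
            continue
        doc["parameters"][param] = [p.pattern for p in cmap.entries[param]]
    if "cancer" in cmap.entries:
        cancer: dict[str, list[str]] = {t: [] for t in CANCER_TIERS}
        for p in cmap.entries["cancer"]:
            cancer[cmap.cancer_tiers[p.pattern]].append(p.pattern)
        doc["cancer"] = cancer
    return doc


def _map_from_dict(doc: Mapping) -> ParameterCodeMap:
    if "parameters" not in doc:
        raise CodeMapError("code-map file lacks a 'parameters' block")
    entries: dict[str, tuple[CodePattern, ...]] = {}
    for param, codes in (doc.get("parameters") or {}).items():
        entries[param] = tuple(CodePattern.from_string(c) for c in codes or ())
    tiers: dict[str, str] = {}
    cancer_block = doc.get("cancer") or {}
    cancer_patterns: list[CodePattern] = []
    for tier, codes in cancer_block.items():
        if tier not in CANCER_TIERS:
            raise CodeMapError(f"unknown cancer tier {tier!r}")
        for c in codes or ():
            pat = CodePattern.from_string(c)
            cancer_patterns.append(pat)
            tiers[pat.pattern] = tier
    if cancer_patterns:
        entries["cancer"] = tuple(cancer_patterns)
    return ParameterCodeMap(
        entries=entries,
        cancer_tiers=tiers,
        version=str(doc.get("version", "unversioned")),
    )


def load_code_map(path: str | Path) -> ParameterCodeMap:
    """Load a parameter code map from its YAML file format."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise CodeMapError(f"code-map file {path} is not a mapping document")
    return _map_from_dict(doc)


def save_code_map(cmap: ParameterCodeMap, path: str | Path) -> None:
    """Write a map back to YAML; ``load(save(m)) == m`` up to pattern order."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_map_to_dict(cmap), fh, sort_keys=False)


def _packaged_map(name: str) -> ParameterCodeMap:
    text = resources.files("raicd.data").joinpath(name).read_text(encoding="utf-8")
    return _map_from_dict(yaml.safe_load(text))


def default_code_map() -> ParameterCodeMap:
    """The packaged default map (synthetic reconstruction, 323 distinct codes)."""
    return _packaged_map("codemap_synthetic_v1.yaml")


def demo_code_map() -> ParameterCodeMap:
    """A small, readable demo map covering every parameter."""
    return _packaged_map("codemap_demo.yaml")
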