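"""Term matching and geographic-region membership.

Parameterized codes compare free-text parameters (diseases, therapies,
research types) against the terms of an access request. The default
comparison is normalized exact equality; an optional child→parent hierarchy
table turns it into subsumption matching, so a request for "breast cancer"
satisfies DS-CANCER when the table records breast cancer ⊂ cancer.

Geographic restrictions (GS-[XX]) are resolved against a region-membership
table (region → member country codes). A small table of common groupings
(EU, EEA, NORTH_AMERICA, AFRICA over ISO-3166 alpha-2 codes) ships with the
package; deployments can load their own.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

__all__ = ["normalize_term", "TermMatcher", "RegionTable"]


def normalize_term(term: str) -> str:
    """Casefold and collapse internal whitespace."""
    return " ".join(term.split()).casefold()


class TermMatcher:
    """Decides whether a request term falls under a code parameter.

    Parameters
    ----------
    hierarchy:
        Optional mapping or (child, parent) pair iterable. A term matches a
        parameter when, after normalization, it equals the parameter or the
        parameter is among its ancestors.
    """

    def __init__(self, hierarchy=None):
        self._parents: dict[str, set[str]] = {}
        if hierarchy is not None:
            items = hierarchy.items() if hasattr(hierarchy, "items") else hierarchy
            for child, parent in items:
                self._parents.setdefault(normalize_term(child), set()).add(
                    normalize_term(parent)
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermMatcher":
        """Load a two-column (term, parent) TSV with a header row."""
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        return cls((r["term"], r["parent"]) for r in rows)

    def ancestors(self, term: str) -> set[str]:
        """All (normalized) transitive ancestors of *term*."""
        seen: set[str] = set()
        stack = [normalize_term(term)]
        while stack:
            for parent in self._parents.get(stack.pop(), ()):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def matches(self, request_term: str, code_parameter: str) -> bool:
        """True when *request_term* is *code_parameter* or a descendant of it."""
        t = normalize_term(request_term)
        p = normalize_term(code_parameter)
        return t == p or p in self.ancestors(request_term)


#: Matcher with no hierarchy: normalized exact equality.
EXACT_MATCHER = TermMatcher()


class RegionTable:
    """region → member lookup for GS-[XX] geographic gates."""

    def __init__(self, members: dict[str, set[str]] | None = None):
        self._members = {
            normalize_term(k): {normalize_term(m) for m in v}
            for k, v in (members or {}).items()
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionTable":
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        members: dict[str, set[str]] = {}
        for r in rows:
            members.setdefault(r["region"], set()).add(r["member"])
        return cls(members)

    @classmethod
    def packaged(cls) -> "RegionTable":
        text = (
            resources.files("consentcodes.data")
            .joinpath("regions.tsv")
            .read_text(encoding="utf-8")
        )
        members: dict[str, set[str]] = {}
        for r in csv.DictReader(text.splitlines(), delimiter="\t"):
            members.setdefault(r["region"], set()).add(r["member"])
        return cls(members)

    def regions(self) -> set[str]:
        return set(self._members)

    def contains(self, region: str, geography: str) -> bool:
        """True when *geography* is the region itself or one of its members."""
        r = normalize_term(region)
        g = normalize_term(geography)
        if r == g:
            return True
        return g in self._members.get(r, ())
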