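"""Top-j overlap between ranked lists and the packaged epidemiology fixtures.

The overlap statistic eta(j) counts the items common to the top j of two
ranked lists.  Shipped fixtures transcribe the Wikipedia-derived PageRank
order of 37 cancer types and 203 cancer drugs together with the GBD-2017
(deaths, DALYs) and GLOBOCAN-2018 (deaths, new cases) cancer rankings, all
with canonical labels so that overlap counts never hinge on word-form
variants ("Hodgkin's" vs "Hodgkin", abbreviations, etc.).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "RankedList",
    "OverlapCurve",
    "canonical_label",
    "overlap_curve",
    "load_fixture",
    "available_fixtures",
]

# Versioned canonicalization table: lowercase variant -> canonical label.
# "Melanoma" and "Skin cancer" are deliberately distinct entries.
_ALIASES: dict[str, str] = {
    "hodgkin lymphoma": "Hodgkin lymphoma",
    "hodgkin's lymphoma": "Hodgkin lymphoma",
    "hodgkin's": "Hodgkin lymphoma",
    "hodgkin": "Hodgkin lymphoma",
    "non-hodgkin lymphoma": "Non-Hodgkin lymphoma",
    "non-hodgkin's lymphoma": "Non-Hodgkin lymphoma",
    "non-hodgkin": "Non-Hodgkin lymphoma",
    "m. myeloma": "Multiple myeloma",
    "nets": "Neuroendocrine tumor",
    "neuroendocrine tumors": "Neuroendocrine tumor",
    "gtd": "Gestational trophoblastic disease",
    "cholangio": "Cholangiocarcinoma",
    "head & neck": "Head and neck cancer",
    "head and neck": "Head and neck cancer",
    "brain": "Brain tumor",
    "bone": "Bone tumor",
    "spinal": "Spinal tumor",
    "adrenal": "Adrenal tumor",
    "soft-tissue": "Soft-tissue sarcoma",
    "soft tissue sarcoma": "Soft-tissue sarcoma",
    "m myeloma": "Multiple myeloma",
    "hydroxycarb.": "Hydroxycarbamide",
    "chlorambuci.": "Chlorambucil",
    "cyclophospha.": "Cyclophosphamide",
    "methylnal": "Methylnaltrexone",
}

#: The 37-cancer canon (subset order irrelevant here; used for suffix resolution).
_CANCER_CANON = {
    "Adrenal tumor", "Anal cancer", "Appendix cancer", "Bladder cancer", "Bone tumor",
    "Brain tumor", "Breast cancer", "Cervical cancer", "Cholangiocarcinoma",
    "Colorectal cancer", "Esophageal cancer", "Gallbladder cancer",
    "Gestational trophoblastic disease", "Head and neck cancer", "Hodgkin lymphoma",
    "Kidney cancer", "Leukemia", "Liver cancer", "Lung cancer", "Melanoma",
    "Mesothelioma", "Multiple myeloma", "Neuroendocrine tumor", "Non-Hodgkin lymphoma",
    "Oral cancer", "Ovarian cancer", "Pancreatic cancer", "Prostate cancer",
    "Skin cancer", "Soft-tissue sarcoma", "Spinal tumor", "Stomach cancer",
    "Testicular cancer", "Thyroid cancer", "Uterine cancer", "Vaginal cancer",
    "Vulvar cancer",
}
_CANON_LOWER = {c.lower(): c for c in _CANCER_CANON}


def canonical_label(label: str) -> str:
    """Map a label variant to its canonical form.

    Unifies apostrophes, resolves known aliases and abbreviations, and
    completes bare cancer names ("Lung" -> "Lung cancer").  Unknown labels
    pass through cleaned but unchanged.
    """
    clean = " ".join(label.replace("’", "'").strip().split())
    low = clean.lower()
    if low in _ALIASES:
        return _ALIASES[low]
    if low in _CANON_LOWER:
        return _CANON_LOWER[low]
    if f"{low} cancer" in _CANON_LOWER:
        return _CANON_LOWER[f"{low} cancer"]
    return clean


@dataclass(frozen=True)
class RankedList:
    """An ordered list of distinct labels with a provenance tag."""

    name: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"ranked list {self.name!r} is empty")
        dupes = {x for x in self.items if list(self.items).count(x) > 1}
        if dupes:
            raise ValueError(f"ranked list {self.name!r} has duplicate labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.items)

    def top(self, j: int) -> tuple[str, ...]:
        return self.items[:j]


@dataclass
class OverlapCurve:
    """eta(j) for j = 1..j_max between two ranked lists."""

    j_values: list[int]
    eta: list[int]
    pair: tuple[str, str]

    def at(self, j: int) -> int:
        return self.eta[self.j_values.index(j)]

    def percent(self, j: int) -> float:
        return 100.0 * self.at(j) / j

    def to_tsv(self, path: str | Path) -> None:
        lines = ["j\teta\tpercent"]
        for j, e in zip(self.j_values, self.eta):
            lines.append(f"{j}\t{e}\t{100.0 * e / j:g}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def overlap_curve(a: RankedList, b: RankedList, j_max: int | None = None) -> OverlapCurve:
    """Number of common items in the top j of two lists, for j = 1..j_max.

    Labels are canonicalized before comparison; a collision created by
    canonicalization (two items mapping to one label) is an error.
    """
    def canon(lst: RankedList) -> list[str]:
        mapped = [canonical_label(x) for x in lst.items]
        seen: dict[str, str] = {}
        for orig, m in zip(lst.items, mapped):
            if m in seen and seen[m] != orig:
                raise ValueError(
                    f"canonicalization collision in {lst.name!r}: "
                    f"{seen[m]!r} and {orig!r} both map to {m!r}"
                )
            seen[m] = orig
        return mapped

    ca, cb = canon(a), canon(b)
    if j_max is None:
        j_max = min(len(ca), len(cb))
    if j_max > min(len(ca), len(cb)):
        raise ValueError(f"j_max={j_max} exceeds the shorter list ({min(len(ca), len(cb))})")
    j_values = list(range(1, j_max + 1))
    eta = [len(set(ca[:j]) & set(cb[:j])) for j in j_values]
    return OverlapCurve(j_values=j_values, eta=eta, pair=(a.name, b.name))


_FIXTURE_FILES = {
    "cancer_types": "cancer_types.tsv",
    "cancer_drugs": "cancer_drugs.tsv",
    "wikipedia_ranking": "wikipedia_pagerank_2017.tsv",
    "wikipedia_cancers": "wikipedia_pagerank_2017.tsv",
    "wikipedia_drugs": "wikipedia_pagerank_2017.tsv",
    "gbd2017_deaths": "gbd2017_deaths.tsv",
    "gbd2017_dalys": "gbd2017_dalys.tsv",
    "globocan2018_deaths": "globocan2018_deaths.tsv",
    "globocan2018_newcases": "globocan2018_newcases.tsv",
}


def available_fixtures() -> list[str]:
    return sorted(_FIXTURE_FILES)


def _read_fixture_rows(filename: str) -> list[dict[str, str]]:
    text = resources.files("regomax.data").joinpath(filename).read_text(encoding="utf-8")
    lines = text.splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:] if line.strip()]


def load_fixture(name: str) -> RankedList:
    """Load a packaged ranking fixture as a :class:`RankedList`.

    ``wikipedia_cancers`` / ``wikipedia_drugs`` expose the cancers-only and
    drugs-only sub-orders of the mixed PageRank ranking.
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    rows = _read_fixture_rows(_FIXTURE_FILES[name])
    if name == "wikipedia_cancers":
        items = [r["label"] for r in rows if r.get("category") == "cancer"]
    elif name == "wikipedia_drugs":
        items = [r["label"] for r in rows if r.get("category") == "drug"]
    else:
        items = [r["label"] for r in rows]
    return RankedList(name=name, items=tuple(items))


def fixture_values(name: str) -> list[tuple[str, float]]:
    """(label, value) pairs for fixtures that carry a numeric column."""
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}")
    rows = _read_fixture_rows(_FIXTURE_FILES[name])
    return [(r["label"], float(r["value"])) for r in rows if r.get("value")]


def load_ranked_list_file(path: str | Path, name: str | None = None) -> RankedList:
    """Read a user-supplied ranked list: TSV with a ``label`` column, or one
    label per line."""
    path = Path(path)
    lines = [l for l in path.read_text(encoding="utf-8").splitlines() if l.strip()]
    if lines and "\t" in lines[0] and "label" in lines[0].split("\t"):
        idx = lines[0].split("\t").index("label")
        items = [l.split("\t")[idx] for l in lines[1:]]
    else:
        items = [l.strip() for l in lines if not l.startswith("#")]
    return RankedList(name=name or path.stem, items=tuple(items))
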