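"""Kic-Kiu couple statistics and the flat-text inhibition-commentary dialect.

The flat-file dialect is line oriented: entries are delimited by ``///``
lines, inhibitor lines start with ``IN\\t`` and may carry a parenthesised
commentary such as ``(#1# mixed inhibition, Kic = 5.0 uM, Kiu = 20 uM #2#)``.
"""
from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .units import CONC_UNITS

log = logging.getLogger(__name__)

CLASSES = ("competitive_dominant", "pure_noncompetitive", "uncompetitive_dominant")

#: headline allowance window for "pure non-competitive" on Kic/Kiu
PNC_WINDOW = (0.5, 2.0)
#: strict preset: equality within typical fitted uncertainty
PNC_WINDOW_STRICT = (0.99, 1.01)

DEFAULT_FOLD_EDGES = (1.0, 1.5, 2.0, 3.0, 5.0, 10.0, 30.0, 100.0, math.inf)


@dataclass(frozen=True)
class RatioRecord:
    """One Kic-Kiu couple; ``kiu=None`` marks a purely competitive report."""

    kic: float
    kiu: float | None
    source_id: str = ""

    def __post_init__(self):
        if not (self.kic > 0):
            raise ValueError("kic must be > 0")
        if self.kiu is not None and not (self.kiu > 0):
            raise ValueError("kiu must be > 0 when bounded")

    @property
    def fold(self) -> float:
        """Fold ratio >= 1: Kiu/Kic when Kiu > Kic, else Kic/Kiu."""
        if self.kiu is None:
            return math.inf
        r = self.kiu / self.kic
        return r if r >= 1 else 1.0 / r


def classify_ratio(record: RatioRecord, pnc_window=PNC_WINDOW) -> str:
    """Class of one couple from the Kic/Kiu ratio and the allowance window."""
    low, high = pnc_window
    if record.kiu is None:
        return "competitive_dominant"
    r = record.kic / record.kiu
    if low <= r <= high:
        return "pure_noncompetitive"
    return "competitive_dominant" if r < low else "uncompetitive_dominant"


@dataclass
class RatioDistribution:
    class_counts: dict
    fold_edges: tuple
    fold_counts: list
    n_total: int

    @property
    def proportions(self) -> dict:
        return {k: round(v / self.n_total, 3) for k, v in self.class_counts.items()}

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "class_counts": self.class_counts,
            "class_proportions": self.proportions,
            "fold_bin_edges": [e if math.isfinite(e) else "inf" for e in self.fold_edges],
            "fold_bin_counts": self.fold_counts,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def ratio_distribution(records, fold_bin_edges=DEFAULT_FOLD_EDGES, pnc_window=PNC_WINDOW) -> RatioDistribution:
    """Class counts plus a histogram of the folded (>= 1) ratio."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    counts = {c: 0 for c in CLASSES}
    for r in records:
        counts[classify_ratio(r, pnc_window)] += 1
    edges = tuple(fold_bin_edges)
    folds = np.array([r.fold for r in records])
    fold_counts = [
        int(np.sum((folds >= lo) & ((folds < hi) | (hi == math.inf))))
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return RatioDistribution(counts, edges, fold_counts, len(records))


# ---------------------------------------------------------------------------
# flat-file parsing
# ---------------------------------------------------------------------------

@dataclass
class FlatfileStats:
    term_counts: dict
    ratio_records: list = field(default_factory=list)


_TERM_PATTERNS = {
    # "competitive" must not be the tail of non[-]competitive or uncompetitive
    "competitive": re.compile(r"(?<!non)(?<!non-)(?<!un)competitive", re.I),
    "noncompetitive": re.compile(r"(?<![a-z])non-?competitive", re.I),
    "mixed": re.compile(r"(?<![a-z])mixed", re.I),
    "uncompetitive": re.compile(r"(?<![a-z])uncompetitive", re.I),
}

_unit_alt = "|".join(sorted(CONC_UNITS, key=len, reverse=True))
_KI_RE = {
    key: re.compile(rf"{key}\s*=\s*(\S+)\s*({_unit_alt})(?![a-zA-Z])", re.I)
    for key in ("Kic", "Kiu")
}
_ID_RE = re.compile(r"^ID\t(\S+)", re.M)


def _extract(regex, line, source_id):
    m = regex.search(line)
    if not m:
        return None
    try:
        return float(m.group(1)) * CONC_UNITS[m.group(2)]
    except (ValueError, KeyError):
        log.warning("malformed constant in %s: %r (skipped)", source_id, m.group(0))
        return None


def parse_flatfile(text: str) -> FlatfileStats:
    """Count inhibition-type terms and extract Kic/Kiu couples.

    Term counting is case-insensitive, unifies "noncompetitive" with
    "non-competitive" and never counts "competitive" inside the longer
    tokens.  Malformed numeric fields are skipped with a warning.
    """
    term_counts = {k: len(p.findall(text)) for k, p in _TERM_PATTERNS.items()}
    records = []
    for n_entry, entry in enumerate(text.split("///")):
        if not entry.strip():
            continue
        m = _ID_RE.search(entry)
        entry_id = m.group(1) if m else f"entry{n_entry}"
        for n_line, line in enumerate(entry.splitlines()):
            if not line.startswith("IN\t"):
                continue
            source_id = f"{entry_id}:{n_line}"
            kic = _extract(_KI_RE["Kic"], line, source_id)
            kiu = _extract(_KI_RE["Kiu"], line, source_id)
            if kic is None:
                if _KI_RE["Kic"].pattern and "kic" in line.lower():
                    pass  # warning already emitted by _extract
                continue
            records.append(RatioRecord(kic, kiu, source_id))
    return FlatfileStats(term_counts, records)


def dedup_records(records):
    """Drop records sharing the same entry id (keep the first occurrence)."""
    seen, out = set(), []
    for r in records:
        key = r.source_id.split(":")[0]
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def records_to_csv(records, path_or_buf) -> None:
    lines = ["source_id,kic_M,kiu_M"]
    for r in records:
        kiu = "" if r.kiu is None else repr(r.kiu)
        lines.append(f"{r.source_id},{r.kic!r},{kiu}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def records_from_csv(path_or_buf):
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    header = lines[0].split(",")
    if header[:3] != ["source_id", "kic_M", "kiu_M"]:
        raise ValueError("unexpected ratio-table header")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        sid, kic, kiu = line.split(",")[:3]
        out.append(RatioRecord(float(kic), float(kiu) if kiu else None, sid))
    return out
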