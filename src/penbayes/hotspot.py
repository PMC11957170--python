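"""Residue-level penetrance aggregation and sliding-window hot-spot detection.

A hot-spot is a stretch of the protein where variant-bearing residues carry
high average Bayesian penetrance: a fixed-width window qualifies when it
holds at least ``min_variants`` variants and the mean penetrance over its
variant-bearing residues exceeds ``min_mean``; overlapping or adjacent
qualifying windows are merged into maximal segments, trimmed to their
outermost variant-bearing residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .posterior_prediction import PenetranceEstimate

__all__ = [
    "DomainMap",
    "HotspotSegment",
    "residue_mean_penetrance",
    "scan_hotspots",
    "annotate_domains",
    "write_segments",
]


@dataclass(frozen=True)
class HotspotSegment:
    """A maximal merged run of qualifying windows, trimmed to variant span."""

    start: int
    end: int
    n_variants: int
    mean_penetrance: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end before start")


class DomainMap:
    """Ordered, non-overlapping named residue intervals (1-based inclusive)."""

    def __init__(self, domains: Iterable[tuple[str, int, int]]) -> None:
        self.domains = sorted(((n, int(s), int(e)) for n, s, e in domains),
                              key=lambda d: d[1])
        prev_end = 0
        for name, start, end in self.domains:
            if start > end:
                raise ValueError(f"domain {name}: start {start} > end {end}")
            if start <= prev_end:
                raise ValueError(f"domain {name} overlaps the previous domain")
            prev_end = end

    def label(self, residue: int) -> str:
        for name, start, end in self.domains:
            if start <= residue <= end:
                return name
        return "inter-domain"


def residue_mean_penetrance(estimates: Iterable[PenetranceEstimate],
                            field: str = "posterior_mean"
                            ) -> dict[int, float]:
    """Unweighted mean penetrance of all variants at each residue."""
    sums: dict[int, list[float]] = {}
    for e in estimates:
        sums.setdefault(e.key[0], []).append(getattr(e, field))
    return {pos: sum(v) / len(v) for pos, v in sorted(sums.items())}


def scan_hotspots(residue_map: Mapping[int, float],
                  variant_positions: Sequence[int],
                  window: int = 100,
                  min_mean: float = 0.4,
                  min_variants: int = 4,
                  dilute: bool = False) -> list[HotspotSegment]:
    """Detect hot-spot segments by a sliding fixed-width window.

    A window [s, s+window-1] qualifies when it contains at least
    ``min_variants`` variants (counted with multiplicity from
    ``variant_positions``) and its mean penetrance strictly exceeds
    ``min_mean``.  By default the mean is taken over variant-bearing
    residues only; ``dilute=True`` divides by the full window width
    instead.  Qualifying windows that overlap or touch are merged; each
    merged segment is trimmed to its first and last variant-bearing residue
    and reported with the variant count and mean recomputed on that span.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not residue_map:
        return []
    counts = Counter(variant_positions)
    positions = sorted(set(residue_map) | set(counts))
    lo, hi = min(positions), max(positions)

    def window_stats(s: int, e: int) -> tuple[int, float]:
        n = sum(c for p, c in counts.items() if s <= p <= e)
        vals = [residue_map[p] for p in residue_map
                if s <= p <= e and p in counts]
        if dilute:
            mean = sum(vals) / (e - s + 1)
        else:
            mean = sum(vals) / len(vals) if vals else 0.0
        return n, mean

    qualifying: list[tuple[int, int]] = []
    for s in range(lo, max(lo, hi - window + 1) + 1):
        e = s + window - 1
        n, mean = window_stats(s, e)
        if n >= min_variants and mean > min_mean:
            qualifying.append((s, e))
    if not qualifying:
        return []

    merged: list[list[int]] = [list(qualifying[0])]
    for s, e in qualifying[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    segments = []
    for s, e in merged:
        span = [p for p in counts if s <= p <= e]
        start, end = min(span), max(span)
        n, mean = window_stats(start, end)
        segments.append(HotspotSegment(start, end, n, mean))
    return segments


def annotate_domains(items, domains: DomainMap):
    """Label residues or segments with their containing domain name.

    Integers are labelled by containment; :class:`HotspotSegment` objects by
    the domain containing their start (or "inter-domain").
    """
    out = []
    for item in items:
        if isinstance(item, HotspotSegment):
            out.append((item, domains.label(item.start)))
        else:
            out.append((int(item), domains.label(int(item))))
    return out


def write_segments(segments: Sequence[HotspotSegment], path,
                   domains: DomainMap | None = None) -> None:
    """Write segments as BED-like CSV (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for seg in segments:
        rows.append({
            "start": seg.start, "end": seg.end,
            "n_variants": seg.n_variants,
            "mean_penetrance": f"{seg.mean_penetrance:.6f}",
            "domain": domains.label(seg.start) if domains else "",
        })
    pd.DataFrame(rows, columns=["start", "end", "n_variants",
                                "mean_penetrance", "domain"]
                 ).to_csv(path, index=False)
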