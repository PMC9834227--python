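"""Internal poly-A capture-site scanning.

Poly-dT priming is meant to anneal to the poly-A tail, but A-rich stretches
inside the transcript body can prime reverse transcription too, producing
coverage far from the annotated transcript end. This module finds candidate
internal sites on the spliced mRNA sequence and computes, per variant, the
effective distance to the nearest capture site a given chemistry could use.

The A-site criterion (maximal run >= min_run, or >= min_frac A content in a
sliding window) is this package's operational definition — the phenomenon is
qualitative in the field and no standard threshold exists — so all three
knobs are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotation import VariantDistance, kit_distance


@dataclass(frozen=True)
class MisprimingSite:
    """One merged A-rich region on a spliced transcript.

    tx_coord is the 0-based spliced position of the region's first base;
    the capture point used for distance geometry is tx_coord itself.
    """

    transcript_id: str
    tx_coord: int
    end: int  # half-open end of the merged region
    run_length: int
    window_A_fraction: float


def _max_a_run(seq: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == "A" else 0
        best = max(best, cur)
    return best


def scan_polyA(
    tx_sequence: str,
    min_run: int = 6,
    window: int = 10,
    min_frac: float = 0.8,
    transcript_id: str = "",
) -> list[MisprimingSite]:
    """Find internal poly-A capture sites on a sense-strand mRNA sequence.

    Reports every maximal A-homopolymer of length >= min_run and every
    length-``window`` interval with A fraction >= min_frac; overlapping hits
    are merged into one site spanning their union. Sites within ``window``
    of the 3' end are excluded (they are the genuine poly-A context).
    """
    seq = tx_sequence.upper()
    n = len(seq)
    if n == 0:
        return []
    intervals: list[tuple[int, int]] = []

    # maximal A runs
    i = 0
    while i < n:
        if seq[i] == "A":
            j = i
            while j < n and seq[j] == "A":
                j += 1
            if j - i >= min_run:
                intervals.append((i, j))
            i = j
        else:
            i += 1

    # windowed A fraction
    if n >= window:
        is_a = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("A")
        counts = np.convolve(is_a.astype(np.int32), np.ones(window, dtype=np.int32), "valid")
        for start in np.nonzero(counts >= min_frac * window)[0]:
            intervals.append((int(start), int(start) + window))

    if not intervals:
        return []
    intervals.sort()
    merged: list[list[int]] = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    sites = []
    for s, e in merged:
        # trim window padding so the site starts and ends on an A
        while s < e and seq[s] != "A":
            s += 1
        while e > s and seq[e - 1] != "A":
            e -= 1
        if s == e:
            continue
        if e > n - window:  # genuine 3'-end poly-A context
            continue
        region = seq[s:e]
        sites.append(
            MisprimingSite(
                transcript_id=transcript_id,
                tx_coord=s,
                end=e,
                run_length=_max_a_run(region),
                window_A_fraction=region.count("A") / len(region),
            )
        )
    return sites


def nearest_capture_site(
    variant_distance: VariantDistance,
    sites: Sequence[MisprimingSite],
    kit_end: str,
    read_length: int = 91,
) -> tuple[Optional[MisprimingSite], int]:
    """Effective distance from a variant to the nearest usable capture site.

    The annotated transcript end is always a capture site; an internal site
    at spliced position c is usable for the 3' chemistry only when the
    variant v lies upstream of it within one read (0 < c - v <= read_length,
    the read runs [c - read_length, c)), and symmetrically for the 5'
    chemistry (read runs [c, c + read_length), so 0 <= v - c < read_length).
    Returns (minimizing internal site or None, effective distance); the
    effective distance never exceeds the annotated-end distance.
    """
    annotated = kit_distance(variant_distance, kit_end)
    v = variant_distance.tx_coord
    best_site: Optional[MisprimingSite] = None
    best = annotated
    for site in sites:
        c = site.tx_coord
        if kit_end in ("three_prime", "3p"):
            d = c - v
            usable = 0 < d <= read_length
        else:
            d = v - c
            usable = 0 <= d < read_length
        if usable and d < best:
            best = d
            best_site = site
    return best_site, best
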