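"""Median/intersection cortex-map generation.

For every (channel, case) pair a classification accuracy is available; per
case, channels whose accuracy is strictly above the case median are the
"meaningful" channels (so at most half the channels per case), and the
intersection of the three per-case sets is the ultimate meaningful channel
set reported for the scalp map.  The even-count median is the mean of the
middle pair, and equality with the median is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classification import ChannelOutcome
from .synthetic_data import CHANNEL_NAMES_24

__all__ = ["CortexMap", "channel_accuracies", "meaningful_channels",
           "ultimate_channels", "build_cortex_map", "render_scalp_svg"]


@dataclass
class CortexMap:
    """Per-channel, per-case accuracies and the derived channel sets."""

    cac: np.ndarray                      # (n_channels, n_cases) accuracies
    medval: np.ndarray                   # per-case medians
    mch: list[set[int]]                  # per-case meaningful channels (1-based)
    umc: list[int]                       # sorted intersection
    channel_names: tuple[str, ...]

    @property
    def umc_names(self) -> list[str]:
        return [self.channel_names[j - 1] for j in self.umc]


def channel_accuracies(outcomes: list[ChannelOutcome],
                       n_channels: int = 24,
                       n_cases: int = 3) -> np.ndarray:
    """Assemble the (n_channels, n_cases) accuracy table, keyed by ids.

    Every (channel 1..n_channels, case 1..n_cases) pair must appear exactly
    once; input order is irrelevant.
    """
    table = np.full((n_channels, n_cases), np.nan)
    for oc in outcomes:
        if oc.channel is None or oc.case is None:
            raise ValueError("outcome lacks channel/case identifiers")
        table[oc.channel - 1, oc.case - 1] = oc.accuracy
    missing = [(int(j) + 1, int(t) + 1)
               for j, t in zip(*np.where(np.isnan(table)))]
    if missing:
        raise ValueError(f"missing (channel, case) outcomes: {missing}")
    return table


def meaningful_channels(case_accuracies: np.ndarray) -> set[int]:
    """1-based channels with accuracy strictly greater than the median."""
    acc = np.asarray(case_accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 channels")
    med = float(np.median(acc))
    return {int(j) + 1 for j in np.flatnonzero(acc > med)}


def ultimate_channels(mch_sets: list[set[int]]) -> list[int]:
    """Sorted intersection of the three per-case meaningful channel sets."""
    if len(mch_sets) != 3:
        raise ValueError(f"expected 3 per-case sets, got {len(mch_sets)}")
    inter = set.intersection(*[set(s) for s in mch_sets])
    return sorted(inter)


def build_cortex_map(outcomes: list[ChannelOutcome],
                     channel_names: tuple[str, ...] = CHANNEL_NAMES_24,
                     n_cases: int = 3) -> CortexMap:
    cac = channel_accuracies(outcomes, n_channels=len(channel_names),
                             n_cases=n_cases)
    medval = np.median(cac, axis=0)
    mch = [meaningful_channels(cac[:, t]) for t in range(n_cases)]
    umc = ultimate_channels(mch) if n_cases == 3 else sorted(
        set.intersection(*mch))
    return CortexMap(cac=cac, medval=medval, mch=mch, umc=umc,
                     channel_names=channel_names)


def render_scalp_svg(cm: CortexMap) -> str:
    """Minimal schematic SVG listing the highlighted channels (presentation)."""
    rows = []
    for i, name in enumerate(cm.channel_names):
        j = i + 1
        fill = "#d62728" if j in cm.umc else "#cccccc"
        x = 40 + (i % 6) * 60
        y = 40 + (i // 6) * 50
        rows.append(
            f'<circle cx="{x}" cy="{y}" r="16" fill="{fill}"/>'
            f'<text x="{x}" y="{y + 4}" font-size="9" text-anchor="middle">{name}</text>'
        )
    body = "\n".join(rows)
    caption = ", ".join(cm.umc_names) or "none"
    return (
        '<svg xmlns="http://www.w3.org/2000/svg" width="400" height="280">\n'
        f"{body}\n"
        f'<text x="20" y="260" font-size="11">meaningful channels: {caption}</text>\n'
        "</svg>\n"
    )
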