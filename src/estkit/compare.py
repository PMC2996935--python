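"""Multi-proteome comparison: best-match rank counting and identity histograms.

Given per-transcript best-hit scores against k reference proteomes,
:func:`rank_best_matches` orders, for each transcript, the proteomes with
a hit by score and counts how often each proteome takes rank 1..k — the
classic "which proteome matches best" table.  :func:`identity_histogram`
bins per-transcript best-alignment identities into percent deciles and
reports the per-proteome mean identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["rank_best_matches", "identity_histogram", "IdentityHistogram"]


def rank_best_matches(
    transcript_hits: Mapping[str, Mapping[str, float]],
    proteome_order: Sequence[str],
    k: int | None = None,
) -> pd.DataFrame:
    """Count, per proteome, how many transcripts rank it 1st..kth best.

    ``transcript_hits`` maps transcript id -> {proteome name: best-hit
    score}; proteomes without a hit for a transcript contribute nothing.
    Equal scores rank in declared ``proteome_order``.  Returns a DataFrame
    with proteome rows, integer rank columns 1..k and a TOTAL column.
    """
    order_index = {name: i for i, name in enumerate(proteome_order)}
    if k is None:
        k = len(proteome_order)
    max_hit = max((len(h) for h in transcript_hits.values()), default=0)
    if k < max_hit:
        raise ValueError(f"k={k} smaller than {max_hit} proteomes with hits")
    counts = np.zeros((len(proteome_order), k), dtype=int)
    for hits in transcript_hits.values():
        for name in hits:
            if name not in order_index:
                raise ValueError(f"unknown proteome {name!r}")
        ranked = sorted(hits, key=lambda n: (-hits[n], order_index[n]))
        for rank, name in enumerate(ranked, start=1):
            counts[order_index[name], rank - 1] += 1
    frame = pd.DataFrame(
        counts, index=list(proteome_order), columns=list(range(1, k + 1))
    )
    frame["TOTAL"] = frame.sum(axis=1)
    return frame


_DECILE_LABELS = tuple(f"{lo}-{lo + 9}" for lo in range(1, 92, 10))  # "1-10" .. "91-100"


@dataclass(frozen=True)
class IdentityHistogram:
    """Decile counts and mean percent identity, per proteome."""

    counts: pd.DataFrame  # proteome rows x decile columns
    mean_identity_pct: pd.Series


def identity_histogram(
    matches: Mapping[str, Mapping[str, float]],
    proteome_order: Sequence[str],
) -> IdentityHistogram:
    """Bin per-transcript best identities (fractions in (0,1]) into deciles.

    Bins are half-open ((0.0,0.1], ..., (0.9,1.0]) so 91-100% is the last
    bin.  Mean identity is reported in percent.
    """
    counts = pd.DataFrame(
        0, index=list(proteome_order), columns=list(_DECILE_LABELS), dtype=int
    )
    sums = {name: 0.0 for name in proteome_order}
    n = {name: 0 for name in proteome_order}
    for hits in matches.values():
        for name, ident in hits.items():
            if not 0.0 < ident <= 1.0:
                raise ValueError(f"identity {ident} outside (0,1]")
            decile = min(int(np.ceil(ident * 10)) - 1, 9)
            counts.loc[name, _DECILE_LABELS[decile]] += 1
            sums[name] += ident
            n[name] += 1
    means = pd.Series(
        {name: (100.0 * sums[name] / n[name]) if n[name] else float("nan") for name in proteome_order}
    )
    return IdentityHistogram(counts, means)
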