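"""Curation of profile score cutoffs from pairwise hmmsearch score collections.

Default noise/trusted cutoffs shipped with public HMM databases are often too
permissive for metagenome-scale annotation, where closely related protein
families co-occur and cross-hit.  The curation procedure here adjusts them
empirically: collect hmmsearch bit scores from pairwise comparisons of a
reference protein collection (subsampled as queries), rank the scores, and
place the cutoff at the mean of the sharpest drop in the ranked score curve —
the point separating the within-family score plateau from the tail of
non-specific hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class CutoffResult:
    """Adjusted cutoff derived from a ranked score series.

    ``interval`` is the (high, low) score pair flanking the sharpest drop and
    ``cutoff`` is their mean; ``drop_index`` is the 0-based rank of the high
    endpoint in the descending score order.  ``degenerate`` marks series with
    no decrease at all (all scores equal).
    """

    cutoff: float
    drop_index: int
    interval: tuple[float, float]
    degenerate: bool = False


def subsample_queries(n_total: int, seed: int) -> tuple[int, np.ndarray]:
    """Pick the query subsample: 10% of the collection, but at least 10 sequences.

    The size is ``max(ceil(0.10 * n_total), 10)`` capped at ``n_total``;
    indices are drawn uniformly without replacement from a generator seeded
    with ``seed``.
    """
    if n_total < 1:
        raise ConfigError("n_total must be >= 1")
    size = min(n_total, max(ceil(0.10 * n_total), 10))
    rng = np.random.default_rng(seed)
    indices = np.sort(rng.choice(n_total, size=size, replace=False))
    return size, indices


def sharpest_drop_cutoff(scores: Sequence[float], window: int = 1) -> CutoffResult:
    """Cutoff = mean of the endpoints of the sharpest decreasing interval.

    Scores are sorted descending; the sharpest decreasing interval is the
    pair ``(s_i, s_{i+window})`` maximizing the drop ``s_i - s_{i+window}``
    (``window=1``: consecutive ranks).  Ties go to the earlier — higher-score,
    hence more conservative — pair.  Input order is irrelevant.
    """
    if len(scores) < 2:
        raise ConfigError("need at least 2 scores to derive a cutoff")
    if window < 1 or window > len(scores) - 1:
        raise ConfigError("window must be in [1, len(scores) - 1]")
    s = np.sort(np.asarray(scores, dtype=float))[::-1]
    if not np.all(np.isfinite(s)):
        raise ConfigError("scores must be finite")
    drops = s[:-window] - s[window:]
    i = int(np.argmax(drops))  # argmax takes the first maximum: earliest pair
    high, low = float(s[i]), float(s[i + window])
    return CutoffResult(
        cutoff=(high + low) / 2.0,
        drop_index=i,
        interval=(high, low),
        degenerate=bool(high == low),
    )
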