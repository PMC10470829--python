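"""In-silico down-sampling of an alignment set (e.g. 90x -> ~30x).

Discarding happens at fragment level so mates are never separated —
discordant-pair evidence depends on intact pairs.  Two modes are exposed,
reflecting the two readings of "randomly discarding reads and retaining
only every third read": a deterministic keep-1-in-3 by sorted fragment id,
and an independent per-fragment Bernoulli subsample under a seed.
"""

from __future__ import annotations

import numpy as np

from .fragments import AlignmentSet


def downsample_every_third(alignments: AlignmentSet) -> AlignmentSet:
    """Keep fragments at id-sorted indices 0, 3, 6, ... (ceil(n/3) kept)."""
    if alignments.n_fragments == 0:
        raise ValueError("cannot down-sample an empty alignment set")
    df = alignments.fragments.sort_values("frag_id").reset_index(drop=True)
    kept = df.iloc[::3].reset_index(drop=True)
    return AlignmentSet(
        kept,
        alignments.reference,
        alignments.read_len,
        alignments.insert_mean,
        alignments.insert_sd,
    )


def downsample_random(
    alignments: AlignmentSet, fraction: float, seed: int
) -> AlignmentSet:
    """Retain each fragment independently with probability ``fraction``."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed % (2**31))
    keep = rng.random(alignments.n_fragments) < fraction
    return alignments.subset(keep)
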