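"""Sliding-window homology profiles and global homology summaries.

Each window of the query is locally aligned to every target and the score is
divided by the same window's local score against the full query itself, so a
self-comparison gives a value of exactly one at every window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import GlobalHomology, ScoringScheme, default_scheme, global_align, local_score

__all__ = ["WindowProfile", "window_profile", "global_homology_table"]


@dataclass(frozen=True)
class WindowProfile:
    query_id: str
    window: int
    step: int
    window_starts: np.ndarray  # 1-based residue index of each window start
    scores: dict[str, np.ndarray]  # target id -> normalised score per window

    def __post_init__(self):
        for target, vals in self.scores.items():
            v = np.asarray(vals, dtype=float)
            if len(v) != len(self.window_starts):
                raise ValueError(f"score array length mismatch for {target}")
            if len(v) and (v.min() < 0 or v.max() > 1 + 1e-9):
                raise ValueError(f"normalised scores outside [0, 1] for {target}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": t, "window_start": int(s), "normalized_score": float(v)}
            for t, vals in self.scores.items()
            for s, v in zip(self.window_starts, vals)
        ]
        return pd.DataFrame(rows, columns=["target", "window_start", "normalized_score"])


def _window_starts(length: int, window: int, step: int) -> list[int]:
    if length <= window:
        return [0]
    return list(range(0, length, step))


def window_profile(
    query: str,
    targets: dict[str, str],
    window: int = 200,
    step: int = 100,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
) -> WindowProfile:
    """Normalised local-alignment profile of ``query`` windows against each
    target.

    Windows are inclusive ranges [s, s+window-1] starting at 1, 1+step, ...;
    a window running past the end is shortened, never discarded.  A query
    shorter than the window yields a single whole-sequence window.  Setting
    ``step == window`` reproduces non-overlapping segments.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not query:
        raise ValueError("query must be non-empty")
    scheme = scheme or default_scheme()

    starts0 = _window_starts(len(query), window, step)
    windows = [query[s : s + window] for s in starts0]
    self_scores = np.array([local_score(w, query, scheme) for w in windows])
    if np.any(self_scores <= 0):
        raise ValueError("window with non-positive self score — cannot normalise")

    scores: dict[str, np.ndarray] = {}
    for name, target in targets.items():
        raw = np.array([local_score(w, target, scheme) for w in windows])
        scores[name] = raw / self_scores

    return WindowProfile(
        query_id=query_id,
        window=window,
        step=step,
        window_starts=np.array(starts0) + 1,
        scores=scores,
    )


def global_homology_table(
    query: str,
    targets: dict[str, str],
    scheme: ScoringScheme | None = None,
) -> tuple[dict[str, GlobalHomology], pd.DataFrame]:
    """Global %identity/%similarity of the query against each target, with
    indels counted against homology (gap columns in the denominator)."""
    results = {name: global_align(query, t, scheme) for name, t in targets.items()}
    table = pd.DataFrame(
        [
            {
                "target": name,
                "pct_identity": g.pct_identity,
                "pct_similarity": g.pct_similarity,
            }
            for name, g in results.items()
        ],
        columns=["target", "pct_identity", "pct_similarity"],
    )
    return results, table
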