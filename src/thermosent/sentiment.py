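"""City-day sentiment index from post-level scores.

Each post carries a sentiment probability score on a 0-100 scale
(0 profoundly negative, 100 strongly positive).  Within a city,
duplicate posts — advertising spam repeated into a city's topic feed —
are removed by exact text match after whitespace normalization, keeping
the earliest copy.  The city-day index is the *median* of the remaining
scores, which resists the extreme-value contamination a mean would
absorb.  City-days with no posts are simply absent (missing in the
panel).

A pluggable scorer interface lets users attach any text-to-score
backend; the packaged :class:`LexiconScorer` is a deterministic stub
used by tests and the synthetic generator only.
"""

from __future__ import annotations

import logging
import re
from typing import Callable, Protocol

import pandas as pd

log = logging.getLogger("thermosent")

_WS_RUN = re.compile(r"\s+")


class Scorer(Protocol):
    """Anything mapping a post text to a sentiment score in [0, 100]."""

    def __call__(self, text: str) -> float: ...


class LexiconScorer:
    """Deterministic toy scorer: 50 + 10·(#positive − #negative) tokens,
    clipped to [0, 100].  A stand-in for an external NLP backend."""

    POSITIVE = frozenset({"good", "great", "happy", "sunny", "nice", "love"})
    NEGATIVE = frozenset({"bad", "awful", "sad", "hot", "cold", "hate"})

    def __call__(self, text: str) -> float:
        toks = _WS_RUN.split(text.strip().lower())
        s = 50 + 10 * (sum(t in self.POSITIVE for t in toks)
                       - sum(t in self.NEGATIVE for t in toks))
        return float(min(100, max(0, s)))


def normalize_text(text: str) -> str:
    """Collapse whitespace runs; case is preserved."""
    return _WS_RUN.sub(" ", str(text).strip())


def dedup_posts(posts: pd.DataFrame, scope: str = "city") -> pd.DataFrame:
    """Drop duplicate posts, keeping the earliest by (date, post_id).

    Two posts are duplicates when their whitespace-normalized texts are
    identical and — under the default ``scope="city"`` — they belong to
    the same city; ``scope="global"`` dedups across cities.  The removal
    count is logged.
    """
    if scope not in ("city", "global"):
        raise ValueError(f"unknown dedup scope {scope!r}")
    df = posts.sort_values(["date", "post_id"], kind="mergesort")
    norm = df["text"].map(normalize_text)
    keys = [norm] if scope == "global" else [df["city_id"], norm]
    keep = ~pd.Series(list(zip(*[k.to_numpy() for k in keys])),
                      index=df.index).duplicated(keep="first")
    removed = int((~keep).sum())
    if removed:
        log.info("dedup removed %d of %d posts", removed, len(df))
    out = df.loc[keep].reset_index(drop=True)
    out.attrs["n_removed"] = removed
    return out


def city_day_sentiment(posts: pd.DataFrame) -> pd.DataFrame:
    """Median sentiment score per (city, date), with contributing counts.

    Expects deduplicated posts.  Even counts use the midpoint of the two
    central order statistics.  Only city-days with at least one post are
    emitted.
    """
    out = (
        posts.groupby(["city_id", "date"], as_index=False, sort=True)
        .agg(sentiment=("score", "median"), n_posts=("score", "size"))
    )
    return out


def score_posts(posts: pd.DataFrame, scorer: Callable[[str], float]) -> pd.DataFrame:
    """Attach scores from a pluggable scorer to an unscored post table."""
    out = posts.copy()
    out["score"] = out["text"].map(scorer).astype(float)
    bad = (out["score"] < 0) | (out["score"] > 100)
    if bad.any():
        raise ValueError("scorer produced values outside [0, 100]")
    return out
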