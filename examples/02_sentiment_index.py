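"""City-day sentiment index: deduplication and the median.

Five posts in one city on one day, two of them advertising spam with
identical text.  Dedup keeps the earliest copy; the city-day index is
the median of the remaining scores, which ignores the extreme 0 that
would drag a mean down.
"""

import pandas as pd

from thermosent import city_day_sentiment, dedup_posts

posts = pd.DataFrame({
    "post_id": ["p1", "p2", "p3", "p4", "p5"],
    "city_id": "C001",
    "date": pd.to_datetime(["2020-07-01"] * 5),
    "text": ["lovely evening by the river",
             "BUY NOW   limited offer",
             "BUY NOW limited offer",       # same ad, whitespace differs
             "stuck in traffic again",
             "terrible terrible day"],
    "score": [78.0, 55.0, 55.0, 44.0, 0.0],
})

deduped = dedup_posts(posts)
index = city_day_sentiment(deduped)

print(f"posts in: {len(posts)}, after dedup: {len(deduped)} "
      f"(removed {posts.shape[0] - deduped.shape[0]} spam copy)")
print(index.to_string(index=False))
print(f"-> median of {sorted(deduped['score'])} = "
      f"{index['sentiment'].iloc[0]}; the mean would be "
      f"{deduped['score'].mean():.2f}, pulled down by the lone 0.")
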