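"""Synthetic forum generator.

Emulates the statistical structure of patient-forum data — gamma-distributed
reads per thread, exponential reply counts, power-law follower/involvement
distributions, preferential-attachment reply targeting, a diurnal/weekday
activity profile with mealtime dips, and token streams with planted
collocations — so that every downstream analysis stage can be exercised and
validated without access to any crawled community data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from ._util import stage_seed

__all__ = [
    "SynthConfig",
    "PostRecord",
    "UserRecord",
    "ForumDataset",
    "SynthConfigError",
    "generate_forum",
    "sample_counts",
    "sample_timestamps",
    "generate_token_stream",
]


class SynthConfigError(ValueError):
    """Raised when a generator configuration field is invalid; names the field."""


# Hour-of-day propensities shaped like patient-forum activity: a rise from
# 4 AM, peaks near 10 AM, 4 PM and 9 PM, dips at the noon and evening
# mealtimes, and low overnight activity.
_DEFAULT_HOURLY = (
    1.0, 0.7, 0.5, 0.4, 0.6, 1.5, 2.5, 4.0, 5.5, 6.5,  # 0-9
    7.5, 6.5, 4.5, 5.5, 6.0, 6.5, 7.2, 5.5, 4.0, 5.5,  # 10-19
    6.5, 7.8, 5.5, 2.5,                                 # 20-23
)

# Weekdays busier than weekends.
_DEFAULT_WEEKDAY = (15.5, 15.5, 15.0, 15.0, 14.5, 12.5, 12.0)

_DEFAULT_COLLOCATIONS = (
    (("blood", "glucose"), 120),
    (("confirmed", "diagnosis"), 90),
    (("surgical", "treatment"), 70),
    (("lung", "cancer"), 60),
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic forum.

    Defaults are sized like a desk-scale disease forum: a few thousand users
    and threads, reads per thread from a right-skewed gamma, reply counts
    exponential with mean ~12, and heavy-tailed follower / involvement
    propensities.
    """

    n_users: int = 2000
    n_threads: int = 5000
    span: tuple[datetime, datetime] = (datetime(2015, 1, 1), datetime(2020, 10, 20))
    reads_gamma: tuple[float, float] = (1.2, 900.0)  # (shape, scale)
    replies_mean: float = 12.0
    follower_exponent: float = 1.8
    involvement_exponent: float = 1.5
    attachment_strength: float = 1.0
    weekday_weights: tuple[float, ...] = _DEFAULT_WEEKDAY
    hourly_weights: tuple[float, ...] = _DEFAULT_HOURLY
    vocab_size: int = 500
    tokens_per_post: int = 25
    collocations: tuple[tuple[tuple[str, str], int], ...] = _DEFAULT_COLLOCATIONS
    topic_lexicon_ref: str = "default"
    couple_reads_replies: bool = False
    forum_name: str = "synthetic-forum"
    seed: int = 0

    def validate(self) -> None:
        if self.n_users <= 0:
            raise SynthConfigError("n_users must be > 0")
        if self.n_threads <= 0:
            raise SynthConfigError("n_threads must be > 0")
        start, end = self.span
        if end <= start:
            raise SynthConfigError("span end must be after span start")
        shape, scale = self.reads_gamma
        if shape <= 0 or scale <= 0:
            raise SynthConfigError("reads_gamma shape and scale must be > 0")
        if self.replies_mean <= 0:
            raise SynthConfigError("replies_mean must be > 0")
        if self.follower_exponent <= 1:
            raise SynthConfigError("follower_exponent must be > 1")
        if self.involvement_exponent <= 1:
            raise SynthConfigError("involvement_exponent must be > 1")
        if self.attachment_strength < 0:
            raise SynthConfigError("attachment_strength must be >= 0")
        for name, weights, k in (
            ("weekday_weights", self.weekday_weights, 7),
            ("hourly_weights", self.hourly_weights, 24),
        ):
            w = np.asarray(weights, dtype=float)
            if w.shape != (k,) or (w < 0).any() or w.sum() <= 0:
                raise SynthConfigError(
                    f"{name} must be {k} nonnegative values with positive sum"
                )
        if self.vocab_size <= 0:
            raise SynthConfigError("vocab_size must be > 0")
        if self.tokens_per_post <= 0:
            raise SynthConfigError("tokens_per_post must be > 0")


@dataclass(frozen=True)
class PostRecord:
    """A thread root or a reply.

    Read/reply counts are populated on thread roots only (``None`` on
    replies), matching how forum crawls expose them.
    """

    post_id: str
    thread_id: str
    author_id: str
    timestamp: datetime
    is_thread_root: bool
    n_reads: int | None
    n_replies: int | None
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class UserRecord:
    user_id: str
    n_followers: int
    n_threads_involved: int


@dataclass
class ForumDataset:
    forum_name: str
    posts: list[PostRecord]
    users: list[UserRecord]

    def posts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "post_id": [p.post_id for p in self.posts],
                "thread_id": [p.thread_id for p in self.posts],
                "author_id": [p.author_id for p in self.posts],
                "timestamp": [p.timestamp for p in self.posts],
                "is_thread_root": [p.is_thread_root for p in self.posts],
                "n_reads": [p.n_reads for p in self.posts],
                "n_replies": [p.n_replies for p in self.posts],
                "tokens": [" ".join(p.tokens) for p in self.posts],
            }
        )

    def users_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "user_id": [u.user_id for u in self.users],
                "n_followers": [u.n_followers for u in self.users],
                "n_threads_involved": [u.n_threads_involved for u in self.users],
            }
        )

    def thread_roots(self) -> list[PostRecord]:
        return [p for p in self.posts if p.is_thread_root]

    def replies(self) -> list[PostRecord]:
        return [p for p in self.posts if not p.is_thread_root]


def sample_counts(family: str, params, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` nonnegative integer counts from a named family.

    gamma(shape, scale) and exponential(mean) draws are rounded to the
    nearest integer (floored at 0); power_law(exponent) is discrete with
    minimum value 1 (Zipf sampling, P(k) proportional to k**-exponent).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if family == "gamma":
        shape, scale = params
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma requires shape > 0 and scale > 0")
        values = rng.gamma(shape, scale, size=n)
        return np.maximum(np.rint(values), 0).astype(np.int64)
    if family == "exponential":
        (mean,) = np.atleast_1d(params).astype(float)
        if mean <= 0:
            raise ValueError("exponential requires mean > 0")
        values = rng.exponential(mean, size=n)
        return np.maximum(np.rint(values), 0).astype(np.int64)
    if family == "power_law":
        (exponent,) = np.atleast_1d(params).astype(float)
        if exponent <= 1:
            raise ValueError("power_law requires exponent > 1")
        if n == 0:
            return np.empty(0, dtype=np.int64)
        return rng.zipf(exponent, size=n).astype(np.int64)
    raise ValueError(f"unknown family: {family!r}")


def sample_timestamps(
    n: int,
    weekday_weights,
    hourly_weights,
    span: tuple[datetime, datetime],
    seed=None,
) -> list[datetime]:
    """Sample ``n`` naive local datetimes inside ``span``.

    Calendar days are weighted by the weekday profile, the hour of day by the
    hourly profile, and minutes/seconds are uniform; empirical weekday and
    hour frequencies therefore converge to the normalized weights.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    start, end = span
    if end <= start:
        raise ValueError("degenerate span: end must be after start")
    wd = np.asarray(weekday_weights, dtype=float)
    hw = np.asarray(hourly_weights, dtype=float)
    if wd.shape != (7,) or (wd < 0).any() or wd.sum() <= 0:
        raise ValueError("weekday_weights must be 7 nonnegative values, not all zero")
    if hw.shape != (24,) or (hw < 0).any() or hw.sum() <= 0:
        raise ValueError("hourly_weights must be 24 nonnegative values, not all zero")
    if n == 0:
        return []

    rng = np.random.default_rng(seed)
    first_day = start.date()
    last_day = (end - timedelta(microseconds=1)).date()
    n_days = (last_day - first_day).days + 1
    day_ords = np.arange(n_days)
    weekdays = np.array(
        [(first_day + timedelta(days=int(d))).weekday() for d in day_ords]
    )
    day_p = wd[weekdays]
    if day_p.sum() <= 0:
        raise ValueError("weekday_weights assign zero mass to every day in span")
    day_p = day_p / day_p.sum()
    hour_p = hw / hw.sum()

    out: list[datetime] = []
    while len(out) < n:
        m = n - len(out)
        days = rng.choice(day_ords, size=m, p=day_p)
        hours = rng.choice(24, size=m, p=hour_p)
        secs = rng.integers(0, 3600, size=m)
        for d, h, s in zip(days, hours, secs):
            ts = datetime.combine(first_day, datetime.min.time()) + timedelta(
                days=int(d), hours=int(h), seconds=int(s)
            )
            if start <= ts < end:
                out.append(ts)
    return out[:n]


def generate_token_stream(
    vocab_size: int,
    collocations,
    length: int,
    seed=None,
) -> list[str]:
    """One pre-tokenized stream with planted adjacent collocations.

    Background tokens are drawn independently and uniformly from a vocabulary
    ``tok0001 .. tokV``; each planted pair is inserted as an adjacent unit
    exactly its planted frequency times, at uniformly random positions.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if vocab_size <= 0:
        raise ValueError("vocab_size must be > 0")
    collocations = list(collocations or [])
    total_planted = sum(int(f) for _, f in collocations)
    if 2 * total_planted > length:
        raise ValueError("planted frequencies exceed length/2")
    if length == 0:
        return []

    rng = np.random.default_rng(seed)
    vocab = np.array([f"tok{i:04d}" for i in range(1, vocab_size + 1)])
    n_background = length - 2 * total_planted
    background = rng.choice(vocab, size=n_background)
    units: list[tuple[str, ...]] = [(t,) for t in background]
    for (u, v), f in collocations:
        units.extend([(str(u), str(v))] * int(f))
    order = rng.permutation(len(units))
    stream: list[str] = []
    for i in order:
        stream.extend(units[i])
    return stream


def _plant_in_posts(post_tokens: list[list[str]], collocations, rng) -> None:
    """Insert each planted pair into random posts, preserving adjacency."""
    n_posts = len(post_tokens)
    for (u, v), f in collocations:
        posts_idx = rng.integers(0, n_posts, size=int(f))
        for pi in posts_idx:
            toks = post_tokens[int(pi)]
            pos = int(rng.integers(0, len(toks) + 1))
            toks[pos:pos] = [str(u), str(v)]


def generate_forum(config: SynthConfig) -> ForumDataset:
    """Generate a full ForumDataset from a validated SynthConfig.

    Thread roots are created in chronological order.  Each root's author is
    chosen with probability proportional to (replies already received +
    attachment_strength * base propensity), where the base propensity is a
    power-law draw governed by ``involvement_exponent``: early authorship is
    propensity-driven, while accumulated replies feed back multiplicatively
    and produce the scale-free reply-network degrees.  Per-thread reply
    counts are independent exponential draws realized as actual reply
    records, so record-level and count-level views agree exactly.
    """
    config.validate()
    rng_users = np.random.default_rng(stage_seed(config.seed, "users"))
    rng_threads = np.random.default_rng(stage_seed(config.seed, "threads"))
    rng_replies = np.random.default_rng(stage_seed(config.seed, "replies"))
    rng_tokens = np.random.default_rng(stage_seed(config.seed, "tokens"))

    user_ids = [f"U{i:06d}" for i in range(1, config.n_users + 1)]
    followers = sample_counts(
        "power_law",
        config.follower_exponent,
        config.n_users,
        rng_users,
    )
    # Power-law activity propensity with the natural finite-size cutoff at
    # the population size: without it a single extreme draw absorbs nearly
    # all activity and most users never appear in the forum at all.
    propensity = np.minimum(
        rng_users.zipf(config.involvement_exponent, size=config.n_users),
        config.n_users,
    ).astype(float)

    # Thread schedule and per-thread marginals.
    thread_times = sorted(
        sample_timestamps(
            config.n_threads,
            config.weekday_weights,
            config.hourly_weights,
            config.span,
            rng_threads,
        )
    )
    reads = np.maximum(
        sample_counts("gamma", config.reads_gamma, config.n_threads, rng_threads), 1
    )
    reply_counts = sample_counts(
        "exponential", config.replies_mean, config.n_threads, rng_threads
    )
    if config.couple_reads_replies:
        # Rank-couple the two marginals: the most-replied thread gets the
        # most reads, preserving both marginal distributions.
        order = np.argsort(np.argsort(reply_counts, kind="stable"), kind="stable")
        reads = np.sort(reads)[order]

    # Preferential-attachment root authorship.
    received = np.zeros(config.n_users, dtype=float)
    base = config.attachment_strength * propensity / propensity.sum() * config.n_users
    root_authors = np.empty(config.n_threads, dtype=np.int64)
    for t in range(config.n_threads):
        w = received + base
        total = w.sum()
        if total <= 0:
            root_authors[t] = rng_threads.integers(0, config.n_users)
        else:
            root_authors[t] = rng_threads.choice(config.n_users, p=w / total)
        received[root_authors[t]] += reply_counts[t]

    # Reply records: authors drawn by the same heavy-tailed activity
    # propensity (uniform authorship would give every user ~equal reply
    # activity, i.e. a Poisson out-degree hump instead of the power-law
    # involvement real forums show); timestamps anywhere within the span.
    total_replies = int(reply_counts.sum())
    author_p = propensity / propensity.sum()
    reply_authors = rng_replies.choice(
        config.n_users, size=total_replies, p=author_p
    )
    reply_times = sample_timestamps(
        total_replies,
        config.weekday_weights,
        config.hourly_weights,
        config.span,
        rng_replies,
    )

    n_posts = config.n_threads + total_replies
    post_tokens = [
        list(rng_tokens.choice(
            np.array([f"tok{i:04d}" for i in range(1, config.vocab_size + 1)]),
            size=config.tokens_per_post,
        ))
        for _ in range(n_posts)
    ]
    _plant_in_posts(post_tokens, config.collocations, rng_tokens)

    posts: list[PostRecord] = []
    tok_iter = iter(post_tokens)
    thread_ids = [f"T{i:06d}" for i in range(1, config.n_threads + 1)]
    for t in range(config.n_threads):
        posts.append(
            PostRecord(
                post_id=f"P{t + 1:07d}",
                thread_id=thread_ids[t],
                author_id=user_ids[int(root_authors[t])],
                timestamp=thread_times[t],
                is_thread_root=True,
                n_reads=int(reads[t]),
                n_replies=int(reply_counts[t]),
                tokens=tuple(next(tok_iter)),
            )
        )
    # Replies are attached thread-by-thread in schedule order.
    ri = 0
    pid = config.n_threads
    for t in range(config.n_threads):
        for _ in range(int(reply_counts[t])):
            pid += 1
            posts.append(
                PostRecord(
                    post_id=f"P{pid:07d}",
                    thread_id=thread_ids[t],
                    author_id=user_ids[int(reply_authors[ri])],
                    timestamp=reply_times[ri],
                    is_thread_root=False,
                    n_reads=None,
                    n_replies=None,
                    tokens=tuple(next(tok_iter)),
                )
            )
            ri += 1

    involvement: dict[str, set[str]] = {u: set() for u in user_ids}
    for p in posts:
        involvement[p.author_id].add(p.thread_id)
    users = [
        UserRecord(
            user_id=u,
            n_followers=int(followers[i]),
            n_threads_involved=len(involvement[u]),
        )
        for i, u in enumerate(user_ids)
    ]
    return ForumDataset(forum_name=config.forum_name, posts=posts, users=users)


def config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from a plain mapping (YAML/JSON friendly)."""
    kwargs = dict(d)
    if "span" in kwargs:
        start, end = kwargs["span"]
        kwargs["span"] = (_coerce_dt(start), _coerce_dt(end))
    if "collocations" in kwargs:
        kwargs["collocations"] = tuple(
            ((str(u), str(v)), int(f)) for (u, v), f in (
                ((c[0][0], c[0][1]), c[1]) for c in kwargs["collocations"]
            )
        )
    known = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(kwargs) - known
    if unknown:
        raise SynthConfigError(f"unknown config fields: {sorted(unknown)}")
    return SynthConfig(**kwargs)


def _coerce_dt(value) -> datetime:
    if isinstance(value, datetime):
        return value
    if isinstance(value, date):
        return datetime.combine(value, datetime.min.time())
    return datetime.fromisoformat(str(value))
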