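"""Reading, writing and cleaning of post/user records (CSV and JSONL)."""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd

from .synth import ForumDataset, PostRecord, UserRecord

__all__ = [
    "POST_COLUMNS",
    "write_posts",
    "write_users",
    "write_dataset",
    "load_posts",
    "load_dataset",
    "clean_posts",
    "CleaningLog",
]

POST_COLUMNS = (
    "post_id",
    "thread_id",
    "author_id",
    "timestamp",
    "is_thread_root",
    "n_reads",
    "n_replies",
    "tokens",
)


def _post_row(p: PostRecord) -> dict:
    return {
        "post_id": p.post_id,
        "thread_id": p.thread_id,
        "author_id": p.author_id,
        "timestamp": p.timestamp.isoformat(),
        "is_thread_root": p.is_thread_root,
        "n_reads": p.n_reads if p.n_reads is not None else "",
        "n_replies": p.n_replies if p.n_replies is not None else "",
        "tokens": " ".join(p.tokens),
    }


def write_posts(dataset: ForumDataset, path, fmt: str = "csv") -> None:
    rows = [_post_row(p) for p in dataset.posts]
    if fmt == "csv":
        pd.DataFrame(rows, columns=list(POST_COLUMNS)).to_csv(path, index=False)
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for r in rows:
                fh.write(json.dumps(r) + "\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def write_users(dataset: ForumDataset, path) -> None:
    dataset.users_frame().to_csv(path, index=False)


def write_dataset(dataset: ForumDataset, outdir, fmt: str = "csv") -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    posts_path = outdir / ("posts.csv" if fmt == "csv" else "posts.jsonl")
    users_path = outdir / "users.csv"
    write_posts(dataset, posts_path, fmt=fmt)
    write_users(dataset, users_path)
    return posts_path, users_path


def _parse_row(row: dict, line_no) -> PostRecord:
    missing = [c for c in POST_COLUMNS if c not in row]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    for col in ("post_id", "thread_id", "author_id"):
        v = row[col]
        if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
            raise ValueError(f"empty {col}")
    ts = row["timestamp"]
    timestamp = ts if isinstance(ts, datetime) else datetime.fromisoformat(str(ts))
    root_raw = str(row["is_thread_root"]).strip().lower()
    if root_raw not in ("true", "false", "1", "0"):
        raise ValueError(f"unparseable is_thread_root: {row['is_thread_root']!r}")
    is_root = root_raw in ("true", "1")

    def _opt_int(v):
        if v is None or str(v).strip() == "" or (isinstance(v, float) and pd.isna(v)):
            return None
        return int(float(v))

    tokens_raw = row["tokens"]
    if tokens_raw is None or (isinstance(tokens_raw, float) and pd.isna(tokens_raw)):
        tokens: tuple[str, ...] = ()
    else:
        tokens = tuple(str(tokens_raw).split())
    return PostRecord(
        post_id=str(row["post_id"]),
        thread_id=str(row["thread_id"]),
        author_id=str(row["author_id"]),
        timestamp=timestamp,
        is_thread_root=is_root,
        n_reads=_opt_int(row["n_reads"]),
        n_replies=_opt_int(row["n_replies"]),
        tokens=tokens,
    )


def load_posts(
    path,
    fmt: str = "csv",
    forum_name: str | None = None,
    rejects_path=None,
) -> ForumDataset:
    """Load a ForumDataset from posts.csv / posts.jsonl.

    Rows with missing fields or unparseable values are routed to a rejects
    list (and optionally a rejects CSV) with reasons, never silently dropped.
    A missing required column is an error naming the column.
    """
    path = Path(path)
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=object, keep_default_na=False)
        missing = [c for c in POST_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        raw_rows = frame.to_dict("records")
    elif fmt == "jsonl":
        raw_rows = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    raw_rows.append(json.loads(line))
    else:
        raise ValueError(f"unknown format: {fmt!r}")

    posts: list[PostRecord] = []
    rejects: list[dict] = []
    for i, row in enumerate(raw_rows):
        try:
            posts.append(_parse_row(row, i))
        except (ValueError, KeyError) as exc:
            rejects.append({"row": i, "reason": str(exc)})
    if rejects_path is not None:
        pd.DataFrame(rejects, columns=["row", "reason"]).to_csv(
            rejects_path, index=False
        )
    dataset = ForumDataset(
        forum_name=forum_name or path.stem,
        posts=posts,
        users=_users_from_posts(posts),
    )
    dataset.rejects = rejects  # type: ignore[attr-defined]
    return dataset


def load_dataset(posts_path, users_path=None, fmt: str = "csv", forum_name=None) -> ForumDataset:
    dataset = load_posts(posts_path, fmt=fmt, forum_name=forum_name)
    if users_path is not None:
        frame = pd.read_csv(users_path)
        dataset.users = [
            UserRecord(
                user_id=str(r.user_id),
                n_followers=int(r.n_followers),
                n_threads_involved=int(r.n_threads_involved),
            )
            for r in frame.itertuples(index=False)
        ]
    return dataset


def _users_from_posts(posts) -> list[UserRecord]:
    involvement: dict[str, set] = {}
    for p in posts:
        involvement.setdefault(p.author_id, set()).add(p.thread_id)
    return [
        UserRecord(user_id=u, n_followers=0, n_threads_involved=len(s))
        for u, s in sorted(involvement.items())
    ]


@dataclass
class CleaningLog:
    removed_bot_posts: int = 0
    removed_missing: int = 0
    recount_adjustments: int = 0
    bot_authors: list = field(default_factory=list)


def clean_posts(
    dataset: ForumDataset,
    bot_author_patterns=(),
    drop_missing: bool = True,
) -> tuple[ForumDataset, CleaningLog]:
    """Remove chatbot posts and incomplete records, keeping counts consistent.

    Posts whose author matches any regex in ``bot_author_patterns`` are
    removed; with ``drop_missing`` posts lacking an id/author/timestamp are
    removed; replies orphaned by the cleaning are kept (network construction
    reports them as rejects) but the per-thread ``n_replies`` of surviving
    roots is recomputed so counts and records agree.
    """
    matchers = [re.compile(p) for p in bot_author_patterns]
    log = CleaningLog()
    kept: list[PostRecord] = []
    bot_authors: set[str] = set()
    for p in dataset.posts:
        if any(m.search(p.author_id) for m in matchers):
            log.removed_bot_posts += 1
            bot_authors.add(p.author_id)
            continue
        if drop_missing and (
            not p.post_id or not p.thread_id or not p.author_id or p.timestamp is None
        ):
            log.removed_missing += 1
            continue
        kept.append(p)
    log.bot_authors = sorted(bot_authors)

    reply_counts: dict[str, int] = {}
    for p in kept:
        if not p.is_thread_root:
            reply_counts[p.thread_id] = reply_counts.get(p.thread_id, 0) + 1
    fixed: list[PostRecord] = []
    for p in kept:
        if p.is_thread_root:
            actual = reply_counts.get(p.thread_id, 0)
            if p.n_replies != actual:
                log.recount_adjustments += 1
                p = PostRecord(
                    post_id=p.post_id,
                    thread_id=p.thread_id,
                    author_id=p.author_id,
                    timestamp=p.timestamp,
                    is_thread_root=True,
                    n_reads=p.n_reads,
                    n_replies=actual,
                    tokens=p.tokens,
                )
        fixed.append(p)
    cleaned = ForumDataset(
        forum_name=dataset.forum_name,
        posts=fixed,
        users=[u for u in dataset.users if u.user_id not in bot_authors],
    )
    return cleaned, log
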