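"""The post record and its JSON-lines serialization.

A corpus is a flat list of :class:`Post` records — one short social-media
message each, carrying an opaque post id, an author id, a conversation
(thread) id, a UTC timestamp and the raw text.  Cleaning and phase
assignment fill in ``clean_tokens`` and ``phase`` later; both are ``None``
on a freshly loaded corpus.

On disk a corpus is JSON lines, one object per post with keys ``post_id``,
``user_id``, ``conversation_id``, ``timestamp`` (ISO-8601, UTC) and
``text``.  Keys are written in that fixed order so identical corpora are
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator


@dataclass
class Post:
    post_id: str
    user_id: str
    conversation_id: str
    timestamp: datetime
    raw_text: str
    clean_tokens: list[str] | None = None
    phase: str | None = None

    def replace(self, **changes) -> "Post":
        return replace(self, **changes)


def _parse_timestamp(value: str) -> datetime:
    ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _format_timestamp(ts: datetime) -> str:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def post_to_record(post: Post) -> dict:
    """Serializable dict for one post (fixed key order)."""
    return {
        "post_id": post.post_id,
        "user_id": post.user_id,
        "conversation_id": post.conversation_id,
        "timestamp": _format_timestamp(post.timestamp),
        "text": post.raw_text,
    }


def post_from_record(record: dict) -> Post:
    return Post(
        post_id=str(record["post_id"]),
        user_id=str(record["user_id"]),
        conversation_id=str(record["conversation_id"]),
        timestamp=_parse_timestamp(record["timestamp"]),
        raw_text=record["text"],
    )


def write_posts_jsonl(posts: Iterable[Post], path: str | Path) -> None:
    """Write posts as JSON lines (UTF-8, one object per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post_to_record(post), ensure_ascii=False))
            fh.write("\n")


def read_posts_jsonl(path: str | Path) -> list[Post]:
    """Read a JSON-lines corpus written by :func:`write_posts_jsonl`."""
    posts = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                posts.append(post_from_record(json.loads(line)))
    return posts


def iter_conversations(posts: Iterable[Post]) -> Iterator[tuple[str, list[Post]]]:
    """Group posts by conversation id, each thread sorted chronologically."""
    threads: dict[str, list[Post]] = {}
    for post in posts:
        threads.setdefault(post.conversation_id, []).append(post)
    for cid in sorted(threads):
        thread = sorted(threads[cid], key=lambda p: (p.timestamp, p.post_id))
        yield cid, thread
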