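"""Adapter trimming, length filtering and tag collapsing.

Reads from all libraries are trimmed, filtered to the configured length
window and collapsed into unique tags carrying per-library counts; tags
whose total count over all libraries falls below the minimum are
discarded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from mirphase.formats import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class UniqueTag:
    """A collapsed small-RNA sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def trim_adapter(sequence: str, adapter: str | None, key_len: int = 8) -> str:
    """Remove the 3' adapter from a read.

    The suffix starting at the leftmost exact match of the adapter's
    first ``key_len`` bases is removed; the read is returned unchanged
    when the adapter is unset or not found.
    """
    if not adapter:
        return sequence
    key = adapter[:key_len]
    idx = sequence.find(key)
    if idx < 0:
        return sequence
    return sequence[:idx]


def collapse(
    reads_per_library: Mapping[str, Iterable[str]],
    config: RunConfig | None = None,
    apply_min_count: bool = True,
) -> list[UniqueTag]:
    """Collapse per-library read streams into unique tags.

    Each read is adapter-trimmed (when ``config.adapter`` is set) and kept
    if its post-trim length lies in [min_len, max_len].  One tag is
    produced per distinct surviving sequence with exact per-library
    counts; tags with total count below ``min_total_count`` are dropped
    (the minimum applies to the total over all libraries).  Output is
    sorted by descending total count, then lexicographic sequence, so
    collapsing is invariant to read order.
    """
    config = config or RunConfig()
    per_lib: dict[str, Counter] = {}
    for library_id, reads in reads_per_library.items():
        counter: Counter = Counter()
        for read in reads:
            seq = trim_adapter(read, config.adapter)
            if config.min_len <= len(seq) <= config.max_len:
                counter[seq] += 1
        per_lib[library_id] = counter

    all_seqs = set()
    for counter in per_lib.values():
        all_seqs.update(counter)

    tags = [
        UniqueTag(
            sequence=seq,
            counts={lib: c[seq] for lib, c in per_lib.items() if c[seq] > 0},
        )
        for seq in all_seqs
    ]
    if apply_min_count:
        kept = [t for t in tags if t.total_count >= config.min_total_count]
        if not kept and tags:
            logger.warning("no tags survive the min_total_count=%d filter", config.min_total_count)
        tags = kept
    tags.sort(key=lambda t: (-t.total_count, t.sequence))
    return tags


def write_tag_table(tags: list[UniqueTag], library_ids: list[str], path: str | Path) -> None:
    """Write the unique-tag table as TSV: sequence, length, per-library counts, total."""
    with open(path, "w") as fh:
        fh.write("sequence\tlength\t" + "\t".join(library_ids) + "\ttotal\n")
        for t in tags:
            row = [t.sequence, str(len(t.sequence))]
            row += [str(t.counts.get(lib, 0)) for lib in library_ids]
            row.append(str(t.total_count))
            fh.write("\t".join(row) + "\n")


def read_tag_table(path: str | Path) -> tuple[list[UniqueTag], list[str]]:
    tags: list[UniqueTag] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        library_ids = header[2:-1]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            counts = {
                lib: int(v) for lib, v in zip(library_ids, parts[2:-1]) if int(v) > 0
            }
            tags.append(UniqueTag(sequence=parts[0], counts=counts))
    return tags, library_ids
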