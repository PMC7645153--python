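"""Per-sample strand-specific CAGE 5'-end tag profiles and CTPM scaling.

A :class:`TagProfile` stores sparse per-bp counts keyed by (contig,
strand).  Normalisation to CTPM (CAGE tags per million mapped) divides
each count by the sample's total mapped tags and multiplies by 1e6, so
the values of one sample always sum to one million.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal

Key = tuple[str, str]  # (contig, strand)


class SignalError(ValueError):
    pass


@dataclass
class TagProfile:
    """Sparse per-bp 5'-end tag counts for one sample."""

    sample_id: str
    counts: dict[Key, dict[int, int]] = field(default_factory=dict)

    @property
    def total_mapped(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())

    def add(self, contig: str, strand: str, position: int, count: int) -> None:
        if position < 0:
            raise SignalError(f"negative coordinate {position}")
        if count <= 0:
            raise SignalError(f"non-positive count {count} at {contig}:{position}")
        d = self.counts.setdefault((contig, strand), {})
        d[position] = d.get(position, 0) + count

    def get(self, contig: str, strand: str) -> dict[int, int]:
        return self.counts.get((contig, strand), {})


@dataclass
class CTPMProfile:
    """Tag profile scaled to tags-per-million mapped."""

    sample_id: str
    values: dict[Key, dict[int, float]]


def load_tags(
    path: str | os.PathLike,
    format: Literal["bed5p", "bedgraph_pair"] = "bed5p",
    sample_id: str | None = None,
) -> TagProfile:
    """Load a per-sample tag profile.

    ``bed5p``: BED6 rows of single-bp 5'-end records, score = count.
    ``bedgraph_pair``: *path* is the ``.plus.bedGraph`` member of a
    (+,-) pair of bedGraph files with integer values; the minus file is
    found by suffix substitution.
    """
    path = str(path)
    if sample_id is None:
        sample_id = os.path.basename(path).split(".")[0]
    profile = TagProfile(sample_id=sample_id)
    if format == "bed5p":
        _read_bed5p(path, profile)
    elif format == "bedgraph_pair":
        if ".plus.bedGraph" in path:
            plus, minus = path, path.replace(".plus.bedGraph", ".minus.bedGraph")
        elif ".minus.bedGraph" in path:
            plus, minus = path.replace(".minus.bedGraph", ".plus.bedGraph"), path
        else:
            raise SignalError(
                f"{path}: bedgraph_pair expects a .plus.bedGraph/.minus.bedGraph pair"
            )
        _read_bedgraph(plus, "+", profile)
        _read_bedgraph(minus, "-", profile)
    else:
        raise SignalError(f"unknown format {format!r}")
    return profile


def _read_bed5p(path: str, profile: TagProfile) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise SignalError(f"{path}:{ln}: BED6 row with {len(f)} fields")
            start, end = int(f[1]), int(f[2])
            if end != start + 1:
                raise SignalError(f"{path}:{ln}: not a single-bp 5' record")
            profile.add(f[0], f[5], start, int(f[4]))


def _read_bedgraph(path: str, strand: str, profile: TagProfile) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            raw = float(f[3])
            if raw != int(raw):
                raise SignalError(f"{path}:{ln}: non-integer bedGraph value {f[3]}")
            count = abs(int(raw))  # minus tracks are often sign-flipped
            if count == 0:
                continue
            for pos in range(start, end):
                profile.add(f[0], strand, pos, count)


def write_bed5p(profile: TagProfile, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for (contig, strand), d in sorted(profile.counts.items()):
            for pos in sorted(d):
                fh.write(f"{contig}\t{pos}\t{pos + 1}\t.\t{d[pos]}\t{strand}\n")


def write_bedgraph_pair(profile: TagProfile, prefix: str | os.PathLike) -> None:
    """Write ``<prefix>.plus.bedGraph`` and ``<prefix>.minus.bedGraph``."""
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        with open(f"{prefix}.{suffix}.bedGraph", "w") as fh:
            for (contig, fstrand), d in sorted(profile.counts.items()):
                if fstrand != strand:
                    continue
                for pos in sorted(d):
                    fh.write(f"{contig}\t{pos}\t{pos + 1}\t{d[pos]}\n")


def write_signal_bedgraph(
    signal: dict[Key, dict[int, float]], prefix: str | os.PathLike
) -> None:
    """Write any (contig, strand)-keyed signal map as a bedGraph pair."""
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        with open(f"{prefix}.{suffix}.bedGraph", "w") as fh:
            for (contig, fstrand), d in sorted(signal.items()):
                if fstrand != strand:
                    continue
                for pos in sorted(d):
                    fh.write(f"{contig}\t{pos}\t{pos + 1}\t{d[pos]:.6g}\n")


def to_ctpm(profile: TagProfile) -> CTPMProfile:
    """Scale raw counts to CAGE tags per million mapped."""
    total = profile.total_mapped
    if total == 0:
        raise SignalError(f"empty library {profile.sample_id!r}")
    scale = 1e6 / total
    values = {
        key: {pos: c * scale for pos, c in d.items()}
        for key, d in profile.counts.items()
    }
    return CTPMProfile(sample_id=profile.sample_id, values=values)


def pool_profiles(
    profiles: Iterable[TagProfile],
    mode: Literal["raw", "ctpm"] = "ctpm",
    contigs: set[str] | None = None,
) -> dict[Key, dict[int, float]]:
    """Per-position sum of raw counts or of CTPM across samples."""
    profiles = list(profiles)
    if not profiles:
        raise SignalError("need at least one profile")
    pooled: dict[Key, dict[int, float]] = {}
    for p in profiles:
        source = p.counts if mode == "raw" else to_ctpm(p).values
        for key, d in source.items():
            if contigs is not None and key[0] not in contigs:
                raise SignalError(
                    f"profile {p.sample_id} has unknown contig {key[0]}"
                )
            out = pooled.setdefault(key, {})
            for pos, v in d.items():
                out[pos] = out.get(pos, 0) + v
    return pooled
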