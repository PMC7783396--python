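"""Dot plots between sequences (or oligo pools rendered as sequence) with
collinear chaining and insertion/orientation inference.

A dot is a shared exact k-mer (default k=15): forward sharing plots on the
main diagonal, reverse-complement sharing on the anti-diagonal. Runs of
near-constant offset are chained into segments; the offset change between
consecutive segments measures insertions in one sequence relative to the
other (to within ~k bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .core import revcomp


@dataclass(frozen=True)
class DotMatch:
    x: int  # query coordinate
    y: int  # target coordinate
    strand: str  # '+' or '-'


@dataclass
class ChainSegment:
    strand: str
    offset: int        # y - x for '+', y + x for '-'
    x_start: int
    x_end: int
    y_start: int
    y_end: int
    n_matches: int


@dataclass
class Insertion:
    where: str  # 'target' or 'query'
    size: int
    x: int  # query coordinate of the junction
    y: int


def dot_matches(query: str, target: str, k: int = 15) -> List[DotMatch]:
    """All (x, y) pairs where query and target share an exact k-mer.

    Reverse-complement sharing yields strand '-'. Output sorted by (x, y).
    Returns an empty list when either sequence is shorter than k.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if k > min(len(query), len(target)):
        return []
    index: Dict[str, List[int]] = {}
    for y in range(len(target) - k + 1):
        km = target[y : y + k]
        if "N" not in km:
            index.setdefault(km, []).append(y)
    matches: List[DotMatch] = []
    for x in range(len(query) - k + 1):
        km = query[x : x + k]
        if "N" in km:
            continue
        for y in index.get(km, ()):
            matches.append(DotMatch(x, y, "+"))
        rc = revcomp(km)
        if rc != km:
            for y in index.get(rc, ()):
                matches.append(DotMatch(x, y, "-"))
    matches.sort(key=lambda m: (m.x, m.y))
    return matches


def chain_segments(
    matches: Sequence[DotMatch], max_gap: int = 2000, min_len: int = 5
) -> Tuple[List[ChainSegment], List[Insertion]]:
    """Greedily chain matches of equal strand and near-constant offset.

    A match extends an open chain when its diagonal offset (y-x forward,
    y+x reverse) differs by at most *max_gap*, it advances in x, and it is
    not separated from the chain tail by more than *max_gap* along x (so a
    chain does not leap across an intervening inversion or deletion). Chains
    with fewer than *min_len* matches are dropped; every match lands in at
    most one segment. Between consecutive surviving segments (by x), an
    offset increase reports an insertion in the target and a decrease an
    insertion in the query, sized by the offset difference.
    """
    chains: List[List[DotMatch]] = []
    for m in sorted(matches, key=lambda m: (m.x, m.y)):
        off = m.y - m.x if m.strand == "+" else m.y + m.x
        best = None
        best_delta = None
        for chain in chains:
            last = chain[-1]
            if last.strand != m.strand or m.x < last.x or m.x - last.x > max_gap:
                continue
            last_off = last.y - last.x if last.strand == "+" else last.y + last.x
            delta = abs(off - last_off)
            if delta <= max_gap and (best_delta is None or delta < best_delta):
                best, best_delta = chain, delta
        if best is None:
            chains.append([m])
        else:
            best.append(m)
    segments: List[ChainSegment] = []
    for chain in chains:
        if len(chain) < min_len:
            continue
        xs = [m.x for m in chain]
        ys = [m.y for m in chain]
        offs = sorted(
            (m.y - m.x if m.strand == "+" else m.y + m.x) for m in chain
        )
        segments.append(
            ChainSegment(
                strand=chain[0].strand,
                offset=offs[len(offs) // 2],
                x_start=min(xs),
                x_end=max(xs),
                y_start=min(ys),
                y_end=max(ys),
                n_matches=len(chain),
            )
        )
    segments.sort(key=lambda s: s.x_start)
    insertions: List[Insertion] = []
    for prev, nxt in zip(segments, segments[1:]):
        if prev.strand != "+" or nxt.strand != "+":
            continue  # offsets are not comparable across strand changes
        dx = nxt.x_start - prev.x_end
        dy = nxt.y_start - prev.y_end
        if dy > dx:
            insertions.append(Insertion("target", dy - dx, nxt.x_start, nxt.y_start))
        elif dx > dy:
            insertions.append(Insertion("query", dx - dy, nxt.x_start, nxt.y_start))
    return segments, insertions


def render_dotplot(matches: Sequence[DotMatch], path, title: str = "") -> None:
    """Scatter the matches, query on x and target on y."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for strand, color in (("+", "#1f77b4"), ("-", "#d62728")):
        xs = [m.x for m in matches if m.strand == strand]
        ys = [m.y for m in matches if m.strand == strand]
        ax.plot(xs, ys, ".", ms=1.5, color=color, label=f"strand {strand}")
    ax.set_xlabel("query (bp)")
    ax.set_ylabel("target (bp)")
    if title:
        ax.set_title(title)
    ax.legend(markerscale=6, fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
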