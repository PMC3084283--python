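"""Precursor discovery on assembled contigs.

Without a reference genome, putative miRNA precursors are hunted in
contigs assembled from the read libraries themselves: a contig carrying
two distinct candidate sequences in different regions may be a hairpin
whose arms produced a miRNA:miRNA* duplex. Folding uses nested base-pair
maximisation (Watson-Crick plus G-U wobble, minimum loop 3) — a
deterministic structural screen in place of a thermodynamic model — and a
duplex is called when the two candidate hits sit on opposite arms of the
hairpin and pair with each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import revcomp
from .similarity import align_pair

logger = logging.getLogger(__name__)

MIN_CONTIG_LEN = 40
MIN_FOLD_LEN = 40
MAX_FOLD_LEN = 200
MIN_LOOP = 3

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    source_tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContigHit:
    candidate_id: str
    contig_id: str
    start: int
    end: int  # 0-based half-open on the + strand of the contig
    strand: str
    identity: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def map_candidates_to_contigs(
    candidates: list[tuple[str, str]],
    contigs: list[Contig],
    min_identity: float = 1.00,
    min_coverage: float = 1.00,
) -> list[ContigHit]:
    """Place candidate sequences on contigs, both strands.

    The default is exact full-length matching (the contigs were assembled
    from the same reads); with ``min_identity`` < 1 the best local-alignment
    placement per contig/strand is reported instead.
    """
    usable = []
    for c in contigs:
        if len(c.sequence) < MIN_CONTIG_LEN:
            logger.warning("contig %s shorter than %d nt, skipped", c.id, MIN_CONTIG_LEN)
            continue
        usable.append(c)
    hits: list[ContigHit] = []
    for cand_id, seq in candidates:
        for contig in usable:
            for strand, probe in (("+", seq), ("-", revcomp(seq))):
                if min_identity >= 1.0 and min_coverage >= 1.0:
                    hits.extend(
                        ContigHit(cand_id, contig.id, s, s + len(probe), strand, 1.0)
                        for s in _occurrences(probe, contig.sequence)
                    )
                else:
                    pa = align_pair(probe, contig.sequence)
                    cov = (pa.aligned_span_a[1] - pa.aligned_span_a[0]) / len(probe)
                    if pa.identity >= min_identity and cov >= min_coverage:
                        hits.append(
                            ContigHit(
                                cand_id, contig.id,
                                pa.aligned_span_b[0], pa.aligned_span_b[1],
                                strand, pa.identity,
                            )
                        )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end, h.candidate_id, h.strand))
    return hits


def _occurrences(needle: str, haystack: str) -> list[int]:
    out = []
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return out
        out.append(pos)
        start = pos + 1


def _disjoint(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[1] <= b[0] or b[1] <= a[0]


def screen_precursor_contigs(hits: list[ContigHit]) -> dict[str, list[ContigHit]]:
    """Contigs with >= 2 distinct candidates in strictly non-overlapping regions."""
    by_contig: dict[str, list[ContigHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    passing = {}
    for contig_id, chits in by_contig.items():
        ok = any(
            a.candidate_id != b.candidate_id and _disjoint(a.interval, b.interval)
            for i, a in enumerate(chits)
            for b in chits[i + 1 :]
        )
        if ok:
            passing[contig_id] = chits
    return passing


@dataclass
class HairpinFold:
    sequence: str
    pairs: set[tuple[int, int]]  # (i, j) with i < j, strictly nested
    arm5: tuple[int, int] | None
    arm3: tuple[int, int] | None
    loop: tuple[int, int] | None
    pairedness5: float
    pairedness3: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_map(self) -> dict[int, int]:
        pm = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def fold_hairpin(sequence: str) -> HairpinFold:
    """Maximal nested base pairing with deterministic traceback.

    Dynamic programme: N(i,j) = max(N(i+1,j), max_k {1 + N(i+1,k-1) + N(k+1,j)})
    over admissible pairs (i,k) with k - i > MIN_LOOP. Traceback prefers
    pairing i with the smallest admissible k that achieves the optimum. Arms
    are the stem flanking the largest hairpin loop, followed outward until a
    branch point.
    """
    n = len(sequence)
    if not (MIN_FOLD_LEN <= n <= MAX_FOLD_LEN):
        raise ValueError(f"fold_hairpin requires {MIN_FOLD_LEN} <= length <= {MAX_FOLD_LEN}, got {n}")
    pairs = nussinov_pairs(sequence)
    arm5, arm3, loop = _locate_arms(pairs, n)
    return HairpinFold(
        sequence=sequence,
        pairs=pairs,
        arm5=arm5,
        arm3=arm3,
        loop=loop,
        pairedness5=_pairedness(arm5, pairs),
        pairedness3=_pairedness(arm3, pairs),
    )


def nussinov_pairs(sequence: str, min_loop: int = MIN_LOOP) -> set[tuple[int, int]]:
    """Optimal nested pair set (usable on any length; fold_hairpin bounds its input)."""
    n = len(sequence)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(sequence[i], sequence[k]):
                    cand = 1 + (dp[i + 1][k - 1] if k - 1 > i else 0) + (
                        dp[k + 1][j] if k + 1 <= j else 0
                    )
                    if cand > best:
                        best = cand
            dp[i][j] = best
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(sequence[i], sequence[k]):
                inner = dp[i + 1][k - 1] if k - 1 > i else 0
                outer = dp[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + outer == dp[i][j]:
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return pairs


def _locate_arms(
    pairs: set[tuple[int, int]], n: int
) -> tuple[tuple[int, int] | None, tuple[int, int] | None, tuple[int, int] | None]:
    if not pairs:
        return None, None, None
    sorted_pairs = sorted(pairs)
    # hairpin loops: pairs with nothing paired strictly inside
    paired_positions = sorted({p for ij in pairs for p in ij})
    loops = []
    for i, j in sorted_pairs:
        if not any(i < p < j for p in paired_positions):
            loops.append((j - i - 1, i, j))
    if not loops:
        return None, None, None
    loops.sort(key=lambda t: (-t[0], t[1]))
    _, i, j = loops[0]
    # walk outward through enclosing pairs until a branch intervenes
    lo, hi = i, j
    while True:
        enclosing = [
            (p, q) for p, q in sorted_pairs if p < lo and q > hi
        ]
        if not enclosing:
            break
        p, q = max(enclosing, key=lambda pq: pq[0])
        branch = any(
            (p < x < lo and y < lo) or (hi < x and y < q and x > hi)
            for x, y in sorted_pairs
            if (x, y) != (p, q)
        )
        if branch:
            break
        lo, hi = p, q
    return (lo, i + 1), (j, hi + 1), (i + 1, j)


def _pairedness(arm: tuple[int, int] | None, pairs: set[tuple[int, int]]) -> float:
    if arm is None or arm[1] <= arm[0]:
        return 0.0
    paired = {p for ij in pairs for p in ij}
    return sum(1 for p in range(arm[0], arm[1]) if p in paired) / (arm[1] - arm[0])


@dataclass
class DuplexCall:
    contig_id: str
    mirna_interval: tuple[int, int] | None
    star_interval: tuple[int, int] | None
    n_pairs_between: int
    verdict: str  # duplex | rejected
    reason: str


def _within_fraction(hit: tuple[int, int], region: tuple[int, int]) -> float:
    lo = max(hit[0], region[0])
    hi = min(hit[1], region[1])
    return max(0, hi - lo) / (hit[1] - hit[0])


def call_duplex(
    fold: HairpinFold,
    hits: list[ContigHit],
    window_start: int = 0,
    min_arm_fraction: float = 0.8,
    min_pair_fraction: float = 0.6,
) -> DuplexCall:
    """Decide whether two candidate hits form a miRNA:miRNA* duplex.

    A duplex needs one hit >= 80% inside the 5' arm, a distinct-candidate hit
    >= 80% inside the 3' arm, and >= 60% of each hit's positions paired with
    positions of the other hit. Hit coordinates are contig coordinates;
    ``window_start`` maps them onto the folded window.
    """
    contig_id = hits[0].contig_id if hits else "?"
    if fold.arm5 is None or fold.arm3 is None:
        return DuplexCall(contig_id, None, None, 0, "rejected", "no hairpin structure")
    local = [
        (h, (h.start - window_start, h.end - window_start))
        for h in hits
        if h.start - window_start >= 0 and h.end - window_start <= len(fold.sequence)
    ]
    on5 = [(h, iv) for h, iv in local if _within_fraction(iv, fold.arm5) >= min_arm_fraction]
    on3 = [(h, iv) for h, iv in local if _within_fraction(iv, fold.arm3) >= min_arm_fraction]
    if not on5 or not on3:
        reason = "same arm" if (on5 or on3) and len(local) >= 2 else "no hit in arm"
        return DuplexCall(contig_id, None, None, 0, "rejected", reason)
    pm = fold.partner_map()
    best: tuple[int, DuplexCall] | None = None
    for h5, iv5 in on5:
        for h3, iv3 in on3:
            if h5.candidate_id == h3.candidate_id or not _disjoint(iv5, iv3):
                continue
            inter5 = sum(
                1 for p in range(*iv5) if p in pm and iv3[0] <= pm[p] < iv3[1]
            )
            inter3 = sum(
                1 for p in range(*iv3) if p in pm and iv5[0] <= pm[p] < iv5[1]
            )
            frac5 = inter5 / (iv5[1] - iv5[0])
            frac3 = inter3 / (iv3[1] - iv3[0])
            n_between = inter5
            if frac5 >= min_pair_fraction and frac3 >= min_pair_fraction:
                call = DuplexCall(
                    contig_id, h5.interval, h3.interval, n_between, "duplex", "opposite arms paired"
                )
                if best is None or n_between > best[0]:
                    best = (n_between, call)
    if best:
        return best[1]
    return DuplexCall(contig_id, None, None, 0, "rejected", "insufficient pairing")


def find_duplexes(
    contigs: list[Contig],
    hits: list[ContigHit],
    pad: int = 15,
    min_arm_fraction: float = 0.8,
    min_pair_fraction: float = 0.6,
) -> dict[str, DuplexCall]:
    """Screen contigs, fold the hit-spanning window, and call duplexes."""
    by_id = {c.id: c for c in contigs}
    passing = screen_precursor_contigs(hits)
    calls: dict[str, DuplexCall] = {}
    for contig_id, chits in passing.items():
        contig = by_id[contig_id]
        lo = max(0, min(h.start for h in chits) - pad)
        hi = min(len(contig.sequence), max(h.end for h in chits) + pad)
        if hi - lo < MIN_FOLD_LEN:
            extra = MIN_FOLD_LEN - (hi - lo)
            lo = max(0, lo - extra // 2)
            hi = min(len(contig.sequence), lo + MIN_FOLD_LEN)
        if hi - lo > MAX_FOLD_LEN:
            logger.warning(
                "contig %s hit window %d nt exceeds fold limit, truncated", contig_id, hi - lo
            )
            hi = lo + MAX_FOLD_LEN
        fold = fold_hairpin(contig.sequence[lo:hi])
        calls[contig_id] = call_duplex(
            fold, chits, window_start=lo,
            min_arm_fraction=min_arm_fraction, min_pair_fraction=min_pair_fraction,
        )
    return calls
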