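"""Brute-force reference implementations used to validate the fast engines.

Each function here recomputes a quantity the production code obtains by a
different route -- exhaustive window checks instead of precomputed site
strings, recursion over all duplex structures instead of the vectorized
dynamic program, per-base coordinate walks instead of interval arithmetic,
pairwise transitive closure instead of the sweep grouping.  They are
deliberately simple and slow; the test suite and the acceptance script run
them on small random instances against the production path.
"""

from __future__ import annotations

from functools import lru_cache

from .energy import EnergyModel

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_PAIRABLE = _WC | {("G", "U"), ("U", "G")}


# ---------------------------------------------------------------------------
# seed scan


def exhaustive_seed_scan(
    mirna_seq: str, transcript: str, include_offset_6mer: bool = False
) -> list[tuple[int, int, str]]:
    """All exact seed-match sites by per-window complementarity checks.

    For every start position, test each category in precedence order by
    explicitly pairing window bases with the corresponding miRNA positions
    (antiparallel Watson-Crick), keeping the best category per start.
    Returns (t_start, t_end, category) triples.
    """

    def wc_block(window: str, positions: range) -> bool:
        # window base k (5'->3') must WC-pair miRNA position positions[-1-k]
        ps = list(positions)
        if len(window) != len(ps):
            return False
        for k, base in enumerate(window):
            p = ps[len(ps) - 1 - k]
            if (mirna_seq[p - 1], base) not in _WC:
                return False
        return True

    if len(mirna_seq) < 8:
        return []
    out = []
    n = len(transcript)
    for i in range(n):
        hit = None
        if i + 8 <= n and wc_block(transcript[i : i + 7], range(2, 9)) \
                and transcript[i + 7] == "A":
            hit = (i, i + 8, "8mer")
        elif i + 7 <= n and wc_block(transcript[i : i + 7], range(2, 9)):
            hit = (i, i + 7, "7mer-m8")
        elif i + 7 <= n and wc_block(transcript[i : i + 6], range(2, 8)) \
                and transcript[i + 6] == "A":
            hit = (i, i + 7, "7mer-A1")
        elif i + 6 <= n and wc_block(transcript[i : i + 6], range(2, 8)):
            hit = (i, i + 6, "6mer")
        elif include_offset_6mer and i + 6 <= n \
                and wc_block(transcript[i : i + 6], range(3, 9)):
            hit = (i, i + 6, "offset-6mer")
        if hit:
            out.append(hit)
    return out


# ---------------------------------------------------------------------------
# duplex free energy


def enumerate_duplex_mfe(mirna_seq: str, window: str, model: EnergyModel) -> float:
    """Minimum free energy over all loop-capped intermolecular structures.

    A structure is a non-empty monotone antiparallel pairing: miRNA indices
    strictly increase while target indices strictly decrease, every pair is
    canonical (WC or G:U), and unpaired stretches between consecutive pairs
    respect the model's per-side loop cap.  Scored with the same energy model
    as the dynamic program: initiation + stacks + loop penalties.  Memoized
    recursion over (last pair); exact, no heuristics.
    """
    m, n = len(mirna_seq), len(window)
    cap = model.max_loop

    def pairable(i: int, j: int) -> bool:
        return (mirna_seq[i], window[j]) in _PAIRABLE

    @lru_cache(maxsize=None)
    def best_extension(i: int, j: int) -> float:
        """Best energy of extending a duplex whose last pair is (i, j)."""
        best = 0.0  # stop here
        for i2 in range(i + 1, min(m, i + 2 + cap)):
            for j2 in range(max(-1, j - 2 - cap) + 1, j):
                if not pairable(i2, j2):
                    continue
                gi, gj = i2 - i - 1, j - j2 - 1
                if gi == 0 and gj == 0:
                    p1 = mirna_seq[i] + window[j]
                    p2 = mirna_seq[i2] + window[j2]
                    step = model.stack_energy(p1, p2)
                else:
                    step = model.loop_energy(gi, gj)
                cand = step + best_extension(i2, j2)
                if cand < best:
                    best = cand
        return best

    mfe = float("inf")
    for i in range(m):
        for j in range(n):
            if pairable(i, j):
                mfe = min(mfe, model.init + best_extension(i, j))
    return mfe


def enumerate_all_duplex_energies(
    mirna_seq: str, window: str, model: EnergyModel
) -> list[float]:
    """Energies of literally every duplex structure (tiny inputs only)."""
    m, n = len(mirna_seq), len(window)
    cap = model.max_loop
    energies: list[float] = []

    def extend(i: int, j: int, energy: float) -> None:
        energies.append(energy)
        for i2 in range(i + 1, m):
            for j2 in range(j):
                gi, gj = i2 - i - 1, j - j2 - 1
                if gi > cap or gj > cap:
                    continue
                if (mirna_seq[i2], window[j2]) not in _PAIRABLE:
                    continue
                if gi == 0 and gj == 0:
                    step = model.stack_energy(
                        mirna_seq[i] + window[j], mirna_seq[i2] + window[j2]
                    )
                else:
                    step = model.loop_energy(gi, gj)
                extend(i2, j2, energy + step)

    for i in range(m):
        for j in range(n):
            if (mirna_seq[i], window[j]) in _PAIRABLE:
                extend(i, j, model.init)
    return energies


# ---------------------------------------------------------------------------
# local alignment


def recursive_alignment_score(mirna_seq: str, target: str, params) -> float:
    """Best local alignment score by exhaustive memoized recursion.

    Mirrors the scoring contract of the alignment engine (complementarity
    substitution scores, position scaling over the miRNA seed positions,
    affine gaps charged open for the first base and extend thereafter) but is
    written as an end-anchored recursion over explicit column types.  Returns
    0.0 when no alignment scores above zero.
    """
    rev = mirna_seq[::-1]
    m, n = len(rev), len(target)
    NEG = float("-inf")

    def sub(r: int, j: int) -> float:
        a, b = rev[r], target[j]
        if (a, b) in _WC:
            s = params.match
        elif (a, b) in {("G", "U"), ("U", "G")}:
            s = params.wobble
        else:
            s = params.mismatch
        if params.scale_start <= (m - r) <= params.scale_end:
            s *= params.scale
        return s

    @lru_cache(maxsize=None)
    def end_sub(r: int, j: int) -> float:
        """Best alignment ending with rev[r] paired opposite target[j]."""
        prev = 0.0
        if r > 0 and j > 0:
            prev = max(
                0.0, end_sub(r - 1, j - 1), end_gap_t(r - 1, j - 1), end_gap_m(r - 1, j - 1)
            )
        return prev + sub(r, j)

    @lru_cache(maxsize=None)
    def end_gap_t(r: int, j: int) -> float:
        """Best alignment ending with target[j] opposite a gap."""
        if j == 0:
            return NEG
        return max(
            end_sub(r, j - 1) + params.gap_open,
            end_gap_t(r, j - 1) + params.gap_extend,
        )

    @lru_cache(maxsize=None)
    def end_gap_m(r: int, j: int) -> float:
        """Best alignment ending with rev[r] opposite a gap."""
        if r == 0:
            return NEG
        return max(
            end_sub(r - 1, j) + params.gap_open,
            end_gap_m(r - 1, j) + params.gap_extend,
        )

    best = 0.0
    for r in range(m):
        for j in range(n):
            best = max(best, end_sub(r, j))
    return best


def enumerate_alignment_score(mirna_seq: str, target: str, params) -> float:
    """Best score over literally all column paths (very small inputs only)."""
    rev = mirna_seq[::-1]
    m, n = len(rev), len(target)
    best = [0.0]

    def sub(r, j):
        a, b = rev[r], target[j]
        if (a, b) in _WC:
            s = params.match
        elif (a, b) in {("G", "U"), ("U", "G")}:
            s = params.wobble
        else:
            s = params.mismatch
        if params.scale_start <= (m - r) <= params.scale_end:
            s *= params.scale
        return s

    def walk(r, j, score, last):
        best[0] = max(best[0], score)
        if r < m and j < n:
            walk(r + 1, j + 1, score + sub(r, j), "S")
        if j < n and last != "M":  # gap consuming target
            cost = params.gap_extend if last == "T" else params.gap_open
            walk(r, j + 1, score + cost, "T")
        if r < m and last != "T":  # gap consuming miRNA
            cost = params.gap_extend if last == "M" else params.gap_open
            walk(r + 1, j, score + cost, "M")

    for r0 in range(m):
        for j0 in range(n):
            walk(r0, j0, 0.0, "")
    return best[0]


# ---------------------------------------------------------------------------
# coordinates and merging


def per_base_map(blocks, strand: str, t_start: int, t_end: int):
    """Map a transcript window one base at a time, then merge runs.

    Independent of the interval mapper: walks every transcript position
    through the block list individually.
    """
    lengths = [b.end - b.start for b in blocks]
    total = sum(lengths)
    positions = []
    for t in range(t_start, t_end):
        f = t if strand == "+" else total - 1 - t
        for b, ln in zip(blocks, lengths):
            if f < ln:
                positions.append(b.start + f)
                break
            f -= ln
    positions.sort()
    runs = []
    for g in positions:
        if runs and g == runs[-1][1]:
            runs[-1] = (runs[-1][0], g + 1)
        else:
            runs.append((g, g + 1))
    return runs


def transitive_overlap_groups(footprints: list[list[tuple[int, int]]]) -> list[set[int]]:
    """Partition site indices by transitive closure of pairwise overlap.

    ``footprints[k]`` is the list of (start, end) genomic pieces of site k
    (single chromosome assumed).  O(n^2) pairwise checks plus BFS closure.
    """
    n = len(footprints)

    def overlap(a, b):
        return any(s1 < e2 and s2 < e1 for s1, e1 in a for s2, e2 in b)

    adjacency = [[overlap(footprints[a], footprints[b]) for b in range(n)] for a in range(n)]
    seen: set[int] = set()
    groups = []
    for start in range(n):
        if start in seen:
            continue
        stack, group = [start], set()
        while stack:
            k = stack.pop()
            if k in group:
                continue
            group.add(k)
            stack.extend(b for b in range(n) if adjacency[k][b] and b not in group)
        seen |= group
        groups.append(group)
    return groups
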