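"""Three independent miRNA binding-site prediction engines.

* ``TS`` -- exact seed matching: scans the transcript for windows that are the
  reverse complement of the miRNA seed (positions 2-7/2-8), reporting the
  canonical site categories (8mer, 7mer-m8, 7mer-A1, 6mer).
* ``RH`` -- duplex hybridization: a dynamic program over miRNA x transcript
  computing minimum-free-energy intermolecular duplexes under a
  nearest-neighbor energy model; the most stable non-overlapping duplexes
  below an energy threshold are reported.
* ``M`` -- position-weighted local alignment: Smith-Waterman-style alignment
  of the reversed miRNA against the transcript with wobble-aware match scores
  and a 5'-seed-region scale factor; surviving alignments are re-scored by
  the duplex energy model.

Engines run with pinned, config-overridable defaults and apply no cross-engine
filtering.  Every site carries a transcript-space footprint, an engine score,
a seed category, and a three-line pairing trace ('|' match, ':' G:U wobble,
' ' mismatch/unpaired, '-' gap).
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np

from .builder import CircStructure, reverse_complement_rna
from .energy import PAIR_INDEX, EnergyModel, encode
from .io import GenomicInterval, MiRNA

logger = logging.getLogger(__name__)

ENGINE_TAGS = ("M", "RH", "TS")

#: Seed categories from strongest to weakest.
SEED_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer", "offset-6mer", "none")
_SEED_RANK = {label: len(SEED_ORDER) - i for i, label in enumerate(SEED_ORDER)}

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


class ConfigurationError(ValueError):
    """Invalid engine parameters."""


def seed_rank(label: str) -> int:
    """Numeric rank of a seed category; higher is stronger."""
    return _SEED_RANK[label]


@dataclass
class PredictedSite:
    """One engine's hit on a circRNA transcript."""

    engine: str
    mirna_name: str
    circ_name: str
    t_start: int
    t_end: int
    score: float
    seed_category: str = "none"
    alignment: str = ""
    # filled in by merge_annotate.sites_to_genomic:
    genomic: tuple[GenomicInterval, ...] = ()
    chrom: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.engine not in ENGINE_TAGS:
            raise ValueError(f"unknown engine tag {self.engine!r}")
        if self.t_end <= self.t_start:
            raise ValueError("site footprint is empty")

    @property
    def primary_interval(self) -> GenomicInterval:
        """5'-most genomic interval of the footprint (transcript 5' end)."""
        if not self.genomic:
            raise ValueError("genomic coordinates not assigned yet")
        return self.genomic[0] if self.strand == "+" else self.genomic[-1]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class TargetScanParams:
    """Seed-scan engine settings."""

    include_offset_6mer: bool = False


@dataclass(frozen=True)
class RNAHybridParams:
    """Duplex-energy engine settings (threshold in kcal/mol)."""

    energy_threshold: float = -20.0


@dataclass(frozen=True)
class MirandaParams:
    """Local-alignment engine settings.

    Alignment points: Watson-Crick match, G:U wobble, mismatch, affine gaps
    (open charged for the first gapped base, extend for each further base).
    Substitution scores at miRNA positions ``scale_start..scale_end`` (1-based
    from the 5' end) are multiplied by ``scale``.  Alignments scoring at least
    ``score_threshold`` are kept only if the duplex energy over their
    footprint is at most ``energy_threshold`` kcal/mol.
    """

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    scale: float = 4.0
    scale_start: int = 2
    scale_end: int = 8
    score_threshold: float = 140.0
    energy_threshold: float = -1.0

    def validate(self) -> None:
        import math

        for f in ("match", "wobble", "mismatch", "gap_open", "gap_extend",
                  "scale", "score_threshold", "energy_threshold"):
            if not math.isfinite(getattr(self, f)):
                raise ConfigurationError(f"non-finite alignment parameter {f!r}")


@dataclass(frozen=True)
class EngineConfig:
    """Bundle of all engine parameters plus the shared energy model."""

    targetscan: TargetScanParams = field(default_factory=TargetScanParams)
    rnahybrid: RNAHybridParams = field(default_factory=RNAHybridParams)
    miranda: MirandaParams = field(default_factory=MirandaParams)
    energy: EnergyModel = field(default_factory=EnergyModel)
    enabled: tuple[str, ...] = ("M", "RH", "TS")

    def with_overrides(self, section: str, **kwargs) -> "EngineConfig":
        return replace(self, **{section: replace(getattr(self, section), **kwargs)})


# ---------------------------------------------------------------------------
# seed classification


def _is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC


def classify_seed(
    mirna_seq: str,
    transcript: str,
    pairing: dict[int, int],
    a1_index: int | None = None,
    include_offset_6mer: bool = False,
) -> str:
    """Seed category of a site given its miRNA-position -> transcript pairing.

    ``pairing`` maps 1-based miRNA positions to transcript indices for paired
    positions (any pair type).  A seed block counts only when it forms a
    contiguous antiparallel Watson-Crick helix: every position must be WC
    paired (a G:U wobble breaks the seed) and consecutive positions must pair
    consecutive target bases.  The target base opposite miRNA position 1 is
    taken from ``a1_index`` when supplied, from the pairing of position 1, or
    as the base 3' of the pairing partner of position 2.
    """

    def wc(p: int) -> bool:
        j = pairing.get(p)
        return (
            j is not None
            and 0 <= j < len(transcript)
            and _is_wc(mirna_seq[p - 1], transcript[j])
        )

    def helix(p_lo: int, p_hi: int) -> bool:
        return all(wc(p) for p in range(p_lo, p_hi + 1)) and all(
            pairing[p + 1] == pairing[p] - 1 for p in range(p_lo, p_hi)
        )

    if len(mirna_seq) < 8:
        return "none"
    m28 = helix(2, 8)
    m27 = helix(2, 7)
    idx = a1_index
    if idx is None:
        idx = pairing.get(1)
    if idx is None and pairing.get(2) is not None:
        idx = pairing[2] + 1
    has_a1 = idx is not None and 0 <= idx < len(transcript) and transcript[idx] == "A"
    if m28 and has_a1:
        return "8mer"
    if m28:
        return "7mer-m8"
    if m27 and has_a1:
        return "7mer-A1"
    if m27:
        return "6mer"
    if include_offset_6mer and helix(3, 8):
        return "offset-6mer"
    return "none"


# ---------------------------------------------------------------------------
# TS engine: exact seed-match scan


def _seed_site_strings(mirna_seq: str) -> list[tuple[str, str]]:
    """(category, target site string 5'->3') in precedence order."""
    rc28 = reverse_complement_rna(mirna_seq[1:8])
    rc27 = reverse_complement_rna(mirna_seq[1:7])
    return [
        ("8mer", rc28 + "A"),
        ("7mer-m8", rc28),
        ("7mer-A1", rc27 + "A"),
        ("6mer", rc27),
    ]


def scan_seed_sites(
    mirna: MiRNA | str,
    transcript: str,
    params: TargetScanParams | None = None,
    circ_name: str = "",
) -> list[PredictedSite]:
    """Exact seed-match scan (TS engine).

    Every transcript start position is tested against the site strings in
    category order; the best (highest-order) category at each start is
    reported once.  N never matches.
    """
    params = params or TargetScanParams()
    name, seq = _mirna_name_seq(mirna)
    if len(seq) < 8:
        return []
    variants = _seed_site_strings(seq)
    if params.include_offset_6mer:
        variants.append(("offset-6mer", reverse_complement_rna(seq[2:8])))
    sites = []
    n = len(transcript)
    for i in range(n):
        for category, site in variants:
            if transcript[i : i + len(site)] == site:
                w = len(site)
                trace = _ts_trace(transcript[i : i + w], category)
                sites.append(
                    PredictedSite(
                        engine="TS",
                        mirna_name=name,
                        circ_name=circ_name,
                        t_start=i,
                        t_end=i + w,
                        score=float(seed_rank(category)),
                        seed_category=category,
                        alignment=trace,
                    )
                )
                break
    return sites


def _ts_trace(window: str, category: str) -> str:
    """Pairing trace for an exact seed match; the A1 base is recognized, not paired."""
    w = len(window)
    paired = w - 1 if category in ("8mer", "7mer-A1") else w
    mid = "|" * paired + " " * (w - paired)
    return f"{window}\n{mid}\n{reverse_complement_rna(window)[::-1]}"


def _mirna_name_seq(mirna: MiRNA | str) -> tuple[str, str]:
    if isinstance(mirna, MiRNA):
        return mirna.name, mirna.sequence
    return "mirna", mirna


# ---------------------------------------------------------------------------
# RH engine: intermolecular duplex minimum free energy


def _duplex_dp(
    mi: np.ndarray, tj: np.ndarray, model: EnergyModel
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Fill the duplex DP.

    ``E[i, j]`` is the minimum free energy of a duplex whose 3'-most miRNA
    pair is (miRNA i, target j); the duplex extends towards smaller i and
    larger j (antiparallel strands).  ``choice[i, j]`` encodes the traceback:
    0 opens a new duplex (initiation), k > 0 is step ``steps[k-1] = (gi, gj)``
    back to the previous pair.
    """
    m, n = len(mi), len(tj)
    cap = model.max_loop
    steps = [(gi, gj) for gi in range(cap + 1) for gj in range(cap + 1)]
    loop = model.loop_matrix()
    stack = model.stack_matrix()
    pidx = PAIR_INDEX[mi[:, None], tj[None, :]]  # (m, n)
    E = np.full((m, n), np.inf)
    choice = np.full((m, n), -1, dtype=np.int32)
    for i in range(m):
        cand = np.full((len(steps) + 1, n), np.inf)
        cand[0, :] = model.init
        for k, (gi, gj) in enumerate(steps):
            pi = i - 1 - gi
            off = 1 + gj
            if pi < 0 or off >= n:
                continue
            width = n - off
            prev = E[pi, off:]
            if gi == 0 and gj == 0:
                pp = pidx[pi, off:]
                cp = pidx[i, :width]
                ok = (pp >= 0) & (cp >= 0)
                cost = np.where(ok, stack[pp.clip(min=0), cp.clip(min=0)], np.inf)
                cand[k + 1, :width] = prev + cost
            else:
                cand[k + 1, :width] = prev + loop[gi, gj]
        best = cand.min(axis=0)
        arg = cand.argmin(axis=0)
        pairable = pidx[i] >= 0
        E[i] = np.where(pairable, best, np.inf)
        choice[i] = np.where(pairable, arg, -1)
    return E, choice, steps


def _traceback(
    choice: np.ndarray, steps: list[tuple[int, int]], i: int, j: int
) -> list[tuple[int, int]]:
    """Pair list (miRNA index, target index) from the 5'-most pair onward."""
    pairs = []
    while True:
        pairs.append((i, j))
        c = choice[i, j]
        if c <= 0:
            break
        gi, gj = steps[c - 1]
        i, j = i - 1 - gi, j + 1 + gj
    pairs.reverse()  # now i ascending, j descending
    return pairs


def duplex_mfe(
    mirna: MiRNA | str, window: str, model: EnergyModel | None = None
) -> float:
    """Minimum free energy (kcal/mol) of any duplex between miRNA and window.

    Returns ``inf`` when no base pair can form.
    """
    model = model or EnergyModel()
    _, seq = _mirna_name_seq(mirna)
    if not seq or not window:
        return float("inf")
    E, _, _ = _duplex_dp(encode(seq), encode(window), model)
    return float(E.min())


def _pair_symbol(a: str, b: str) -> str:
    if (a, b) in _WC:
        return "|"
    if (a, b) in _GU:
        return ":"
    return " "


def _duplex_trace(mirna_seq: str, transcript: str, pairs: list[tuple[int, int]]) -> str:
    """Three-line trace: target 5'->3' on top, miRNA 3'->5' below."""
    top, mid, bot = [], [], []
    rev = pairs[::-1]  # j ascending, i descending
    for k, (i, j) in enumerate(rev):
        if k:
            pi, pj = rev[k - 1]
            gj = j - pj - 1          # unpaired target bases
            gi = pi - i - 1          # unpaired miRNA bases
            for step in range(max(gi, gj)):
                top.append(transcript[pj + 1 + step] if step < gj else "-")
                bot.append(mirna_seq[pi - 1 - step] if step < gi else "-")
                mid.append(" ")
        top.append(transcript[j])
        bot.append(mirna_seq[i])
        mid.append(_pair_symbol(mirna_seq[i], transcript[j]))
    return "".join(top) + "\n" + "".join(mid) + "\n" + "".join(bot)


def hybridize_mfe(
    mirna: MiRNA | str,
    transcript: str,
    model: EnergyModel | None = None,
    e_threshold: float = -20.0,
    circ_name: str = "",
) -> list[PredictedSite]:
    """Duplex-energy scan (RH engine).

    Reports locally optimal duplexes with free energy <= ``e_threshold`` whose
    target footprints do not overlap, chosen greedily best-first (ties: lower
    energy, then smaller footprint start).
    """
    if e_threshold >= 0:
        raise ConfigurationError("duplex energy threshold must be negative (kcal/mol)")
    model = model or EnergyModel()
    name, seq = _mirna_name_seq(mirna)
    if not seq or not transcript:
        return []
    mi, tj = encode(seq), encode(transcript)
    E, choice, steps = _duplex_dp(mi, tj, model)
    ii, jj = np.where(E <= e_threshold)
    candidates = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        pairs = _traceback(choice, steps, i, j)
        t_start = min(p[1] for p in pairs)
        t_end = max(p[1] for p in pairs) + 1
        candidates.append((float(E[i, j]), t_start, t_end, pairs))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    sites: list[PredictedSite] = []
    taken: list[tuple[int, int]] = []
    for energy, t_start, t_end, pairs in candidates:
        if any(t_start < e and s < t_end for s, e in taken):
            continue
        taken.append((t_start, t_end))
        pairing = {i + 1: j for i, j in pairs}
        category = classify_seed(seq, transcript, pairing)
        sites.append(
            PredictedSite(
                engine="RH",
                mirna_name=name,
                circ_name=circ_name,
                t_start=t_start,
                t_end=t_end,
                score=energy,
                seed_category=category,
                alignment=_duplex_trace(seq, transcript, pairs),
            )
        )
    sites.sort(key=lambda s: (s.t_start, s.t_end))
    return sites


# ---------------------------------------------------------------------------
# M engine: position-weighted gapped local alignment


@dataclass
class _Alignment:
    score: float
    columns: list[tuple[int | None, int | None]]  # (miRNA index, target index)

    @property
    def j_range(self) -> tuple[int, int]:
        js = [j for _, j in self.columns if j is not None]
        return min(js), max(js) + 1


def best_local_alignment(
    mirna_seq: str, target: str, params: MirandaParams | None = None
) -> _Alignment | None:
    """Best complementarity-scored local alignment (Gotoh, affine gaps).

    The miRNA is aligned 3'->5' against the target 5'->3' (antiparallel).
    Returns None when no alignment scores above zero.
    """
    params = params or MirandaParams()
    params.validate()
    rev = mirna_seq[::-1]
    m, n = len(rev), len(target)
    if m == 0 or n == 0:
        return None

    def sub(r: int, j: int) -> float:
        a, b = rev[r], target[j]
        if (a, b) in _WC:
            s = params.match
        elif (a, b) in _GU:
            s = params.wobble
        else:
            s = params.mismatch
        p = m - r  # 1-based miRNA position from the 5' end
        if params.scale_start <= p <= params.scale_end:
            s *= params.scale
        return s

    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in miRNA (consumes target)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target (consumes miRNA)
    best, bi, bj = 0.0, 0, 0
    for r in range(1, m + 1):
        for j in range(1, n + 1):
            X[r][j] = max(H[r][j - 1] + params.gap_open, X[r][j - 1] + params.gap_extend)
            Y[r][j] = max(H[r - 1][j] + params.gap_open, Y[r - 1][j] + params.gap_extend)
            diag = max(H[r - 1][j - 1], X[r - 1][j - 1], Y[r - 1][j - 1])
            h = diag + sub(r - 1, j - 1)
            H[r][j] = max(0.0, h, X[r][j], Y[r][j])
            if H[r][j] > best:
                best, bi, bj = H[r][j], r, j
    if best <= 0:
        return None
    # traceback
    columns: list[tuple[int | None, int | None]] = []
    r, j, state = bi, bj, "H"
    while r > 0 and j > 0:
        if state == "H":
            if H[r][j] == 0:
                break
            if H[r][j] == X[r][j]:
                state = "X"
                continue
            if H[r][j] == Y[r][j]:
                state = "Y"
                continue
            columns.append((r - 1, j - 1))
            diag = max(H[r - 1][j - 1], X[r - 1][j - 1], Y[r - 1][j - 1])
            if diag == H[r - 1][j - 1]:
                state = "H"
            elif diag == X[r - 1][j - 1]:
                state = "X"
            else:
                state = "Y"
            r, j = r - 1, j - 1
        elif state == "X":
            columns.append((None, j - 1))
            if X[r][j] == H[r][j - 1] + params.gap_open:
                state = "H"
            j -= 1
        else:
            columns.append((r - 1, None))
            if Y[r][j] == H[r - 1][j] + params.gap_open:
                state = "H"
            r -= 1
    columns.reverse()
    return _Alignment(score=best, columns=columns)


def _alignment_trace(mirna_seq: str, target: str, aln: _Alignment) -> str:
    rev = mirna_seq[::-1]
    top, mid, bot = [], [], []
    for r, j in aln.columns:
        top.append(target[j] if j is not None else "-")
        bot.append(rev[r] if r is not None else "-")
        if r is not None and j is not None:
            mid.append(_pair_symbol(rev[r], target[j]))
        else:
            mid.append(" ")
    return "".join(top) + "\n" + "".join(mid) + "\n" + "".join(bot)


def local_align_score(
    mirna: MiRNA | str,
    transcript: str,
    params: MirandaParams | None = None,
    model: EnergyModel | None = None,
    circ_name: str = "",
) -> list[PredictedSite]:
    """Position-weighted local-alignment scan (M engine).

    All non-overlapping local maxima with score >= ``score_threshold`` are
    collected greedily best-first; each surviving alignment is re-scored with
    the duplex energy model over its footprint and kept only if that energy is
    at most ``energy_threshold``.
    """
    params = params or MirandaParams()
    params.validate()
    model = model or EnergyModel()
    name, seq = _mirna_name_seq(mirna)
    m = len(seq)
    hits: list[tuple[int, _Alignment]] = []

    def scan_segment(lo: int, hi: int) -> None:
        if hi - lo <= 0:
            return
        aln = best_local_alignment(seq, transcript[lo:hi], params)
        if aln is None or aln.score < params.score_threshold:
            return
        j0, j1 = aln.j_range
        hits.append((lo, aln))
        scan_segment(lo, lo + j0)
        scan_segment(lo + j1, hi)

    scan_segment(0, len(transcript))
    sites = []
    for lo, aln in hits:
        j0, j1 = aln.j_range
        t_start, t_end = lo + j0, lo + j1
        energy = duplex_mfe(seq, transcript[t_start:t_end], model)
        if energy > params.energy_threshold:
            continue
        pairing = {}
        a1_index = None
        for r, j in aln.columns:
            if r is None or j is None:
                continue
            p = m - r  # 1-based miRNA position
            if p == 1:
                a1_index = lo + j
            if (seq[p - 1], transcript[lo + j]) in _WC | _GU:
                pairing[p] = lo + j
        category = classify_seed(seq, transcript, pairing, a1_index=a1_index)
        sites.append(
            PredictedSite(
                engine="M",
                mirna_name=name,
                circ_name=circ_name,
                t_start=t_start,
                t_end=t_end,
                score=aln.score,
                seed_category=category,
                alignment=_alignment_trace(seq, transcript, aln),
            )
        )
    sites.sort(key=lambda s: (s.t_start, s.t_end))
    return sites


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class EngineOutput:
    """Union of engine results plus per-pair failure records."""

    sites: list[PredictedSite]
    failures: list[str]


def _dedupe(sites: list[PredictedSite]) -> list[PredictedSite]:
    seen = set()
    out = []
    for s in sites:
        key = (s.engine, s.mirna_name, s.circ_name, s.t_start, s.t_end)
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


def _pair_sites(payload) -> tuple[list[PredictedSite], list[str]]:
    """Run all enabled engines on one (miRNA, circRNA) pair."""
    mirna_name, mirna_seq, circ_name, sequence, config = payload
    mirna = MiRNA(name=mirna_name, sequence=mirna_seq)
    sites: list[PredictedSite] = []
    failures: list[str] = []
    runners = {
        "TS": lambda: scan_seed_sites(mirna, sequence, config.targetscan, circ_name),
        "RH": lambda: hybridize_mfe(
            mirna, sequence, config.energy,
            config.rnahybrid.energy_threshold, circ_name,
        ),
        "M": lambda: local_align_score(
            mirna, sequence, config.miranda, config.energy, circ_name
        ),
    }
    for tag in config.enabled:
        try:
            sites.extend(runners[tag]())
        except ConfigurationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"{tag}:{mirna_name}:{circ_name}: {exc}")
    return _dedupe(sites), failures


def run_engines(
    mirnas: list[MiRNA],
    structures: dict[str, CircStructure] | list[CircStructure],
    config: EngineConfig | None = None,
    workers: int = 1,
) -> EngineOutput:
    """Run all enabled engines over every (miRNA, circRNA) pair.

    Results are identical whether run serially or with N worker processes:
    work units are dispatched in a fixed order and collected order-preserving,
    then sorted canonically.
    """
    config = config or EngineConfig()
    if isinstance(structures, dict):
        circ_list = list(structures.values())
    else:
        circ_list = list(structures)
    work = [
        (m.name, m.sequence, c.name, c.sequence, config)
        for c in sorted(circ_list, key=lambda c: c.name)
        for m in sorted(mirnas, key=lambda m: m.name)
    ]
    sites: list[PredictedSite] = []
    failures: list[str] = []
    if workers <= 1 or len(work) <= 1:
        results = map(_pair_sites, work)
    else:
        executor = ProcessPoolExecutor(max_workers=workers)
        results = executor.map(_pair_sites, work, chunksize=max(1, len(work) // (4 * workers)))
    for pair_sites, pair_failures in results:
        sites.extend(pair_sites)
        failures.extend(pair_failures)
    if workers > 1 and len(work) > 1:
        executor.shutdown()
    for msg in failures:
        logger.error("engine failure: %s", msg)
    sites.sort(key=lambda s: (s.circ_name, s.mirna_name, s.engine, s.t_start, s.t_end))
    return EngineOutput(sites=sites, failures=failures)
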