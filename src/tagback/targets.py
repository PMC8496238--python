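"""Candidate target enumeration, off-target search, QC, feature expansion.

Off-target enumeration is PAM-anchored: every genomic window (both strands)
whose PAM satisfies the motif's PAM pattern is a potential protospacer, and
a window is a hit when its Hamming distance to the spacer is within the
error budget.  The search is exact — an exhaustive scan over PAM-anchored
windows, vectorized with numpy — so tiny-genome brute-force oracles can
check it verbatim.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FeatureNotEditableError
from .genome import Feature, Genome
from .motif import TargetMotif, _char_class, _expand_segments, reverse_complement
from .scoring import (
    OffTargetHit,
    QCThresholds,
    get_ontarget_scorer,
    gc_percent,
    hsu_zhang_aggregate,
    hsu_zhang_single,
    polyt_score,
)

MAX_EXPANSION_DEFAULT = 4096


@dataclass
class CandidateTarget:
    """A genomic cut site: spacer+PAM window, strand, metrics, QC verdict."""

    contig: str
    start: int  # 0-based half-open over spacer+PAM
    end: int
    strand: str
    spacer: str
    pam: str
    cut_position: int
    metrics: dict = field(default_factory=dict)
    passes_qc: bool | None = None
    failure_reasons: tuple[str, ...] = ()

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.contig, self.start, self.strand)

    @property
    def spacer_interval(self) -> tuple[int, int]:
        """Plus-strand coordinates of the spacer alone (without the PAM)."""
        pam_len = len(self.pam)
        spacer_left = (self.strand == "+") == (self._pam_side == "three_prime")
        if spacer_left:
            return (self.start, self.end - pam_len)
        return (self.start + pam_len, self.end)

    _pam_side: str = field(default="three_prime", repr=False)


def _cut_position(start: int, end: int, strand: str, pam_side: str, pam_len: int,
                  cut_offset: int | None) -> int:
    c = cut_offset or 0
    if pam_side == "three_prime":
        if strand == "+":
            return end - pam_len - c
        return start + pam_len + c
    if strand == "+":
        return start + pam_len + c
    return end - pam_len - c


def _iter_matches(contig_seq: str, motif: TargetMotif):
    """Yield (start, end, strand, spacer, pam) for every motif match, both strands."""
    rc = reverse_complement(contig_seq)
    n = len(contig_seq)
    for fixed in motif.expansions():
        for m in fixed.scan.finditer(contig_seq):
            window = m.group(1)
            spacer, pam = fixed.decompose(window)
            yield (m.start(), m.start() + fixed.total_len, "+", spacer, pam)
        for m in fixed.scan.finditer(rc):
            window = m.group(1)
            spacer, pam = fixed.decompose(window)
            start = n - m.start() - fixed.total_len
            yield (start, start + fixed.total_len, "-", spacer, pam)


def scan_targets(
    genome: Genome, motif: TargetMotif, region: Feature | tuple[str, int, int] | None = None
) -> list[CandidateTarget]:
    """All motif matches whose spacer+PAM window overlaps ``region`` by >= 1 bp.

    ``region`` may be a Feature (its expanded bounds are used), a
    ``(contig, start, end)`` tuple, or None for the whole genome.  Sorted by
    (contig, start, strand).
    """
    if region is None:
        spans = [(c, 0, len(s)) for c, s in genome.contigs.items()]
    elif isinstance(region, Feature):
        spans = [(region.contig, region.expanded_start, region.expanded_end)]
    else:
        spans = [region]
    out: list[CandidateTarget] = []
    seen: set[tuple] = set()
    for contig, rstart, rend in spans:
        seq = genome.contigs[contig]
        for start, end, strand, spacer, pam in _iter_matches(seq, motif):
            if end <= rstart or start >= rend:
                continue
            key = (contig, start, end, strand, spacer)
            if key in seen:  # distinct quantifier assignments can coincide
                continue
            seen.add(key)
            out.append(
                CandidateTarget(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    spacer=spacer,
                    pam=pam,
                    cut_position=_cut_position(
                        start, end, strand, motif.pam_side, len(pam), motif.cut_offset_sense
                    ),
                    _pam_side=motif.pam_side,
                )
            )
    out.sort(key=lambda t: (t.contig, t.start, t.strand))
    return out


# ---------------------------------------------------------------------------
# Off-target index


class OffTargetIndex:
    """PAM-anchored protospacer matrix for fast exhaustive Hamming queries.

    For each contig, strand, and fixed motif expansion, stores the window
    start coordinates and a (windows x spacer_len) uint8 matrix of
    protospacers read 5'->3' in spacer sense.
    """

    def __init__(self, genome: Genome, motif: TargetMotif):
        self.genome = genome
        self.motif = motif
        self._blocks: list[dict] = []
        # one block set per distinct (spacer_len, pam_len) geometry
        geometries = sorted({(f.spacer_len, f.pam_len, f.pam_side) for f in motif.expansions()})
        for L, P, pam_side in geometries:
            pam_pat = re.compile("(?=(" + _pam_pattern(motif, P) + "))")
            for contig, seq in genome.contigs.items():
                n = len(seq)
                for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                    sarr = np.frombuffer(s.encode(), dtype=np.uint8)
                    if pam_side == "three_prime":
                        win_starts = [
                            m.start() - L for m in pam_pat.finditer(s) if m.start() >= L
                        ]
                        proto_offset = 0
                    else:
                        win_starts = [
                            m.start() for m in pam_pat.finditer(s) if m.start() + P + L <= n
                        ]
                        proto_offset = P
                    if not win_starts:
                        continue
                    ws = np.asarray(win_starts, dtype=np.int64)
                    view = np.lib.stride_tricks.sliding_window_view(sarr, L)
                    protos = view[ws + proto_offset]
                    # map local-strand window starts to plus-strand coordinates
                    total = L + P
                    plus_starts = ws if strand == "+" else n - ws - total
                    self._blocks.append(
                        {
                            "contig": contig,
                            "strand": strand,
                            "spacer_len": L,
                            "pam_len": P,
                            "pam_side": pam_side,
                            "plus_starts": np.asarray(plus_starts, dtype=np.int64),
                            "protos": np.ascontiguousarray(protos),
                        }
                    )

    def query(
        self,
        spacer: str,
        max_errors: int,
        exclude_site: tuple[str, int, str] | None = None,
    ) -> list[OffTargetHit]:
        """All PAM-compatible windows within ``max_errors`` mismatches."""
        hits: list[OffTargetHit] = []
        seen: set[tuple] = set()
        sp = np.frombuffer(spacer.encode(), dtype=np.uint8)
        for blk in self._blocks:
            L = blk["spacer_len"]
            if L != len(spacer):
                continue
            mism = blk["protos"] != sp
            dists = mism.sum(axis=1)
            sel = np.flatnonzero(dists <= max_errors)
            for i in sel:
                start = int(blk["plus_starts"][i])
                site = (blk["contig"], start, blk["strand"])
                if exclude_site is not None and site == exclude_site:
                    continue
                if site in seen:  # overlapping PAM-length geometries
                    continue
                seen.add(site)
                idxs = np.flatnonzero(mism[i])
                if blk["pam_side"] == "three_prime":
                    positions = tuple(int(j) + 1 for j in idxs)  # 1 = PAM-distal = 5' end
                else:
                    positions = tuple(L - int(j) for j in reversed(idxs))
                hits.append(
                    OffTargetHit(
                        contig=blk["contig"],
                        position=start,
                        strand=blk["strand"],
                        mismatch_positions=positions,
                    )
                )
        hits.sort(key=lambda h: (h.contig, h.position, h.strand))
        return hits

    def min_distance(self, spacer: str) -> int:
        """Smallest Hamming distance from ``spacer`` to any compatible window."""
        best = len(spacer) + 1
        sp = np.frombuffer(spacer.encode(), dtype=np.uint8)
        for blk in self._blocks:
            if blk["spacer_len"] != len(spacer) or not len(blk["plus_starts"]):
                continue
            d = int((blk["protos"] != sp).sum(axis=1).min())
            best = min(best, d)
        return best


def _pam_pattern(motif: TargetMotif, pam_len: int) -> str:
    """Union regex body over all PAM expansions of the given length."""
    alts = []
    for pm in _expand_segments(motif.pam_segments):
        if sum(n for _, n in pm) == pam_len:
            alts.append("".join(_char_class(c) * n for c, n in pm))
    if not alts:
        raise AssertionError("no PAM expansion at the fixed length")
    return alts[0] if len(alts) == 1 else "(?:" + "|".join(alts) + ")"


def find_offtargets(
    genome: Genome,
    spacer: str,
    motif: TargetMotif,
    max_errors: int,
    exclude_site: tuple[str, int, str] | None = None,
    index: OffTargetIndex | None = None,
) -> list[OffTargetHit]:
    """Genome-wide near-matches of ``spacer`` at PAM-compatible windows."""
    if max_errors < 0:
        raise ValueError("max_errors must be >= 0")
    if index is None:
        index = OffTargetIndex(genome, motif)
    return index.query(spacer, max_errors, exclude_site)


# ---------------------------------------------------------------------------
# QC


def qc_evaluate(
    target: CandidateTarget,
    hits: list[OffTargetHit],
    thresholds: QCThresholds = QCThresholds(),
    ontarget_scorer: str = "surrogate",
) -> CandidateTarget:
    """Populate metrics and the pass/fail verdict on a candidate.

    The errors metric is the minimum mismatch count over off-target hits
    (inf when there are none); a guide fails uniqueness when any site lies
    within ``thresholds.min_uniqueness`` mismatches.
    """
    spacer = target.spacer
    scored = [
        dataclasses.replace(
            h, per_hit_score=hsu_zhang_single(h.mismatch_positions, len(spacer))
        )
        for h in hits
    ]
    polyt = polyt_score(spacer)
    gc = gc_percent(spacer)
    errors = min((h.n_mismatches for h in scored), default=math.inf)
    ontarget = get_ontarget_scorer(ontarget_scorer)(spacer, "")
    aggregate = hsu_zhang_aggregate(scored)
    reasons = []
    if polyt > thresholds.polyt_max:
        reasons.append("polyT")
    if not thresholds.gc_min <= gc <= thresholds.gc_max:
        reasons.append("GC")
    if errors <= thresholds.min_uniqueness:
        reasons.append("errors")
    if ontarget < thresholds.ontarget_min:
        reasons.append("ontarget")
    if aggregate < thresholds.offtarget_min:
        reasons.append("offtarget")
    target.metrics = {
        "polyt": polyt,
        "gc": gc,
        "errors": errors,
        "ontarget": ontarget,
        "offtarget_aggregate": aggregate,
    }
    target.passes_qc = not reasons
    target.failure_reasons = tuple(reasons)
    return target


def _evaluate_candidate(
    target: CandidateTarget,
    index: OffTargetIndex,
    thresholds: QCThresholds,
    ontarget_scorer: str,
) -> CandidateTarget:
    hits = index.query(target.spacer, thresholds.errors_max, exclude_site=target.site)
    # the homologous site on a sister haplotype is the same locus, not an
    # off-target: drop hits at the target's own coordinates within its group
    group = set(index.genome.group_of(target.contig))
    if len(group) > 1:
        hits = [
            h for h in hits
            if not (h.contig in group and h.position == target.start
                    and h.strand == target.strand)
        ]
    return qc_evaluate(target, hits, thresholds, ontarget_scorer)


def passing_targets(
    genome: Genome,
    motif: TargetMotif,
    thresholds: QCThresholds = QCThresholds(),
    region=None,
    index: OffTargetIndex | None = None,
    ontarget_scorer: str = "surrogate",
) -> list[CandidateTarget]:
    """Scan + QC in one pass; returns all evaluated candidates."""
    if index is None:
        index = OffTargetIndex(genome, motif)
    cands = scan_targets(genome, motif, region)
    return [_evaluate_candidate(t, index, thresholds, ontarget_scorer) for t in cands]


# ---------------------------------------------------------------------------
# Feature expansion


def _expansion_schedule(feature: Feature, contig_len: int, max_expansion: int, step: int):
    """Yield (start, end) bounds alternating one step left, one step right."""
    left = right = 0
    while True:
        start = max(0, feature.start - left)
        end = min(contig_len, feature.end + right)
        yield start, end
        if end - start >= max_expansion or (start == 0 and end == contig_len):
            return
        # prefer symmetric growth: grow the side that lags, left first on ties
        grow_left = left <= right and feature.start - left > 0
        if grow_left:
            left += step
        elif feature.end + right < contig_len:
            right += step
        else:
            left += step


def expand_feature(
    genome: Genome,
    feature: Feature,
    motif: TargetMotif,
    thresholds: QCThresholds = QCThresholds(),
    max_expansion: int = MAX_EXPANSION_DEFAULT,
    step: int = 50,
    index: OffTargetIndex | None = None,
    ontarget_scorer: str = "surrogate",
) -> Feature:
    """Smallest symmetric-preference expansion containing a passing target.

    Bounds grow alternately one step left, one step right (default 50 bp)
    until at least one QC-passing candidate lies wholly inside; total width
    never exceeds ``max_expansion``.  Raises
    :class:`FeatureNotEditableError` when no expansion works.
    """
    contig_len = len(genome.contigs[feature.contig])
    if index is None:
        index = OffTargetIndex(genome, motif)
    # all candidates the widest window could ever contain, evaluated lazily
    lo = max(0, feature.start - max_expansion)
    hi = min(contig_len, feature.end + max_expansion)
    pool = scan_targets(genome, motif, (feature.contig, lo, hi))
    evaluated: dict[tuple, CandidateTarget] = {}
    for start, end in _expansion_schedule(feature, contig_len, max_expansion, step):
        if end - start > max_expansion:
            break
        for t in pool:
            if t.start < start or t.end > end:
                continue
            key = (t.start, t.strand, t.end)
            if key not in evaluated:
                evaluated[key] = _evaluate_candidate(t, index, thresholds, ontarget_scorer)
            if evaluated[key].passes_qc:
                return feature.with_expansion(start, end)
    raise FeatureNotEditableError(
        f"feature {feature.name!r}: no QC-passing target within a {max_expansion} bp expansion"
    )


def check_arm_polymorphism(
    haplotype_a_arm: str, haplotype_b_arm: str, max_mismatch_fraction: float = 0.05
) -> bool:
    """True iff the arms' ungapped mismatch fraction is within the cap.

    Length differences (indels in the arm region) are flagged as failing by
    raising ValueError rather than guessing an alignment.
    """
    if len(haplotype_a_arm) != len(haplotype_b_arm):
        raise ValueError(
            f"arm length mismatch ({len(haplotype_a_arm)} vs {len(haplotype_b_arm)}): "
            "indel in arm region"
        )
    mism = sum(a != b for a, b in zip(haplotype_a_arm, haplotype_b_arm))
    return mism / len(haplotype_a_arm) <= max_mismatch_fraction


def rank_targets(
    candidates: list[CandidateTarget], feature: Feature | None = None
) -> list[CandidateTarget]:
    """Passing candidates first, best-scored first; fully deterministic.

    Order within the passing block: descending off-target aggregate, then
    descending on-target, then ascending polyT run, then cut-site proximity
    to the feature midpoint; ties broken by (contig, start, strand).
    """
    mid = (feature.start + feature.end) / 2 if feature is not None else None

    def key(t: CandidateTarget):
        m = t.metrics or {}
        prox = abs(t.cut_position - mid) if mid is not None else 0.0
        return (
            0 if t.passes_qc else 1,
            -m.get("offtarget_aggregate", 0.0),
            -m.get("ontarget", 0.0),
            m.get("polyt", 0.0),
            prox,
            t.contig,
            t.start,
            t.strand,
        )

    return sorted(candidates, key=key)


# ---------------------------------------------------------------------------
# Editability sweep

SWEEP_SIZES_DEFAULT = (1, 2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)


def editability_sweep(
    genome: Genome,
    n_loci: int,
    feature_sizes=SWEEP_SIZES_DEFAULT,
    motif: TargetMotif | None = None,
    thresholds: QCThresholds = QCThresholds(),
    seed: int = 0,
    max_expansion: int = MAX_EXPANSION_DEFAULT,
    overlap: str = "spacer_pam",
    ontarget_scorer: str = "surrogate",
) -> pd.DataFrame:
    """Direct vs indirect editability proportions across feature sizes.

    Random loci are sampled genome-wide; at each size a feature centered on
    the locus is tested for Direct editability (>= 1 bp overlap with a
    passing target; ``overlap`` selects spacer+PAM or spacer-only windows)
    and Indirect editability (a passing target fits together with the
    feature inside a window no wider than ``max_expansion``).
    """
    if motif is None:
        raise ValueError("a motif is required")
    if n_loci > genome.total_length:
        raise ValueError("n_loci exceeds available genome positions")
    rng = np.random.default_rng(seed)
    index = OffTargetIndex(genome, motif)
    passing = [
        t
        for t in passing_targets(genome, motif, thresholds, index=index,
                                 ontarget_scorer=ontarget_scorer)
        if t.passes_qc
    ]
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in genome.contigs:
        ts = [t for t in passing if t.contig == contig]
        if overlap == "spacer_only":
            ivals = [t.spacer_interval for t in ts]
        else:
            ivals = [(t.start, t.end) for t in ts]
        by_contig[contig] = (
            np.asarray([a for a, _ in ivals], dtype=np.int64),
            np.asarray([b for _, b in ivals], dtype=np.int64),
        )

    names = list(genome.contigs)
    lengths = np.asarray([len(genome.contigs[c]) for c in names], dtype=np.float64)
    ci = rng.choice(len(names), size=n_loci, p=lengths / lengths.sum())
    centers = [int(rng.integers(0, lengths[i])) for i in ci]

    rows = []
    for size in feature_sizes:
        n_direct = n_indirect = 0
        for i, center in zip(ci, centers):
            contig = names[i]
            clen = int(lengths[i])
            fs = max(0, min(center - size // 2, clen - size))
            fe = min(clen, fs + size)
            starts, ends = by_contig[contig]
            if starts.size == 0:
                continue
            direct = bool(((starts < fe) & (ends > fs)).any())
            span = np.maximum(ends, fe) - np.minimum(starts, fs)
            indirect = direct or bool((span <= max_expansion).any())
            n_direct += direct
            n_indirect += indirect
        rows.append(
            {
                "size": size,
                "direct_prop": n_direct / n_loci,
                "indirect_prop": n_indirect / n_loci,
            }
        )
    return pd.DataFrame(rows)
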