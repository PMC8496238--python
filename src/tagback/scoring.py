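"""Guide-quality metrics.

* polyT: longest strand-specific T homopolymer run in the spacer.  With the
  default threshold 4.5, runs of five or more fail.
* GC: percent G+C of the spacer.
* Hsu-Zhang: the position-weighted off-target penalty of Hsu et al. 2013
  (the "MIT" scheme).  Each genomic near-match is scored in [0,100] from its
  mismatch positions; per-hit scores aggregate into a 0-100 guide
  specificity score.
* CFD: table-driven cutting-frequency-determination score; the penalty
  table is user-supplied (TSV), not bundled.
* On-target: a pluggable scorer registry.  The built-in "surrogate" scorer
  is a deterministic rule-based stand-in (polyT and GC-deviation penalties)
  and is NOT the Azimuth trained model; outputs are labeled accordingly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Sequence

from .errors import CFDTableError

# Experimentally derived per-position mismatch weights of Hsu et al. 2013,
# position 1 = PAM-distal end of a 20 nt SpCas9 spacer.
HSU_WEIGHTS: tuple[float, ...] = (
    0.0, 0.0, 0.014, 0.0, 0.0,
    0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732,
    0.828, 0.615, 0.804, 0.685, 0.583,
)


@dataclass(frozen=True)
class QCThresholds:
    """Default guide quality-control gates.

    ``errors_max`` is the off-target enumeration budget (sites searched up
    to this many mismatches); ``min_uniqueness`` is the pass rule derived
    from it: a guide fails when any non-identical genomic site lies within
    ``min_uniqueness`` mismatches.
    """

    polyt_max: float = 4.5
    gc_min: float = 25.0
    gc_max: float = 75.0
    errors_max: int = 5
    min_uniqueness: int = 1
    ontarget_min: float = 45.0
    offtarget_min: float = 90.0

    def __post_init__(self) -> None:
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic near-match of a spacer, with per-position mismatch detail."""

    contig: str
    position: int  # window start, 0-based, plus-strand coordinates
    strand: str
    mismatch_positions: tuple[int, ...]  # 1 = PAM-distal
    per_hit_score: float = field(default=0.0, compare=False)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def polyt_score(spacer: str) -> float:
    """Length of the longest consecutive run of 'T' in the spacer as written."""
    best = run = 0
    for ch in spacer:
        run = run + 1 if ch == "T" else 0
        best = max(best, run)
    return float(best)


def gc_percent(seq: str) -> float:
    """100 x (#G + #C) / length."""
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def _weight_at(position: int, spacer_len: int) -> float:
    """Hsu weight for a mismatch at ``position`` (1 = PAM-distal).

    Spacers longer than 20 extend the PAM-distal end with weight 0; shorter
    spacers use the PAM-proximal tail of the vector.
    """
    idx = position - 1 + (len(HSU_WEIGHTS) - spacer_len)
    if idx < 0:
        return 0.0
    return HSU_WEIGHTS[idx]


def hsu_zhang_single(mismatch_positions: Sequence[int], spacer_len: int = 20) -> float:
    """Per-hit Hsu-Zhang score in [0,100].

    100 x prod(1-W[p]) x 1/(((19-d)/19)*4 + 1) x 1/n^2, where d is the mean
    pairwise distance between mismatch positions.  A perfect match scores
    100; a single mismatch scores 100*(1-W[p]).
    """
    positions = sorted(set(int(p) for p in mismatch_positions))
    if len(positions) != len(mismatch_positions):
        raise ValueError("mismatch positions must be unique")
    for p in positions:
        if not 1 <= p <= spacer_len:
            raise ValueError(f"mismatch position {p} outside [1, {spacer_len}]")
    n = len(positions)
    if n == 0:
        return 100.0
    score = 100.0
    for p in positions:
        score *= 1.0 - _weight_at(p, spacer_len)
    if n > 1:
        d = sum(abs(a - b) for a, b in combinations(positions, 2)) / (n * (n - 1) / 2)
        score *= 1.0 / (((19.0 - d) / 19.0) * 4.0 + 1.0)
        score *= 1.0 / (n * n)
    return score


def hsu_zhang_aggregate(hits: Sequence) -> float:
    """Aggregate guide specificity: 100*100 / (100 + sum of per-hit scores).

    Accepts :class:`OffTargetHit` objects or bare per-hit scores; the
    on-target site itself must not be among the hits.  Empty -> 100.
    """
    total = 0.0
    for h in hits:
        total += h.per_hit_score if hasattr(h, "per_hit_score") else float(h)
    return 100.0 * 100.0 / (100.0 + total)


# ---------------------------------------------------------------------------
# CFD (table-driven)


def load_cfd_table(path: str | Path) -> dict:
    """Read a CFD penalty table from TSV.

    Columns: ``mismatch_type`` (e.g. ``A:C`` = guide base A opposite
    genomic C, or the literal ``PAM``), ``position`` (1 = PAM-distal; for
    PAM rows the PAM sequence itself), ``penalty``.
    """
    p = Path(path)
    if not p.is_file():
        raise CFDTableError(
            f"CFD table {path} not found; CFD scoring is disabled without a table"
        )
    table: dict = {"mm": {}, "pam": {}}
    with open(p) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            kind = row["mismatch_type"].strip()
            if kind.upper() == "PAM":
                table["pam"][row["position"].strip().upper()] = float(row["penalty"])
            else:
                table["mm"][(kind.upper(), int(row["position"]))] = float(row["penalty"])
    return table


def cfd_score(spacer: str, offtarget_protospacer: str, pam: str, table: dict) -> float:
    """Product of per-position mismatch penalties times the PAM penalty.

    1.0 for a perfect match with a canonical PAM.  Missing entries raise
    :class:`CFDTableError` naming the key.
    """
    if table is None:
        raise CFDTableError("no CFD table supplied; CFD scoring is disabled")
    if len(spacer) != len(offtarget_protospacer):
        raise ValueError("spacer and protospacer lengths differ")
    score = 1.0
    for i, (g, t) in enumerate(zip(spacer, offtarget_protospacer), start=1):
        if g == t:
            continue
        key = (f"{g}:{t}", i)
        try:
            score *= table["mm"][key]
        except KeyError:
            raise CFDTableError(f"CFD table missing entry mismatch_type={key[0]} position={i}")
    pam_key = pam.upper()
    if pam_key in table["pam"]:
        score *= table["pam"][pam_key]
    elif table["pam"]:
        # fall back on the NGG-style wildcard row when present
        wildcard = "N" + pam_key[1:]
        if wildcard in table["pam"]:
            score *= table["pam"][wildcard]
        else:
            raise CFDTableError(f"CFD table missing PAM entry {pam_key}")
    return score


# ---------------------------------------------------------------------------
# On-target scorer seam

_ONTARGET_REGISTRY: dict[str, Callable[[str, str], float]] = {}


def register_ontarget_scorer(name: str, fn: Callable[[str, str], float]) -> None:
    _ONTARGET_REGISTRY[name] = fn


def get_ontarget_scorer(name: str) -> Callable[[str, str], float]:
    try:
        return _ONTARGET_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown on-target scorer {name!r}; registered: {sorted(_ONTARGET_REGISTRY)}"
        )


def surrogate_ontarget(spacer: str, context: str = "") -> float:
    """Rule-based on-target stand-in (NOT the Azimuth trained model).

    100 minus a 20-point penalty per T beyond a 4-run and one point per
    percent GC deviation from 50, clipped to [0,100].  Deterministic; kept
    only so the QC gate has a working default scorer.
    """
    penalty = 20.0 * max(0.0, polyt_score(spacer) - 4.0) + abs(gc_percent(spacer) - 50.0)
    return min(100.0, max(0.0, 100.0 - penalty))


register_ontarget_scorer("surrogate", surrogate_ontarget)

ONTARGET_SURROGATE_NOTE = "on-target scores from rule-based surrogate (not Azimuth)"
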