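"""Validation-primer design and in-silico PCR genotyping.

Candidate primers are enumerated by a sliding window over role-specific
regions of the wild-type (+), knock-out (delta) and add-back (AB) genome
states, weighted by closeness to Tm/GC/length optima, and assembled into a
cross-genome set (sF/sR spanning the locus, oF/oR junction pairs, iF/iR
internal pairs, AmpF/AmpR donor-amplification pair) by simulated annealing
over role assignments.  In-silico PCR on each genome state predicts the
colony-PCR banding pattern that discriminates the three genotypes.

Melting temperatures come from a nearest-neighbor duplex model
(SantaLucia unified ΔH/ΔS parameters with an entropic salt correction),
not a full folding-thermodynamics calculation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PrimerRoleError
from .genome import Genome, GenomeState
from .motif import reverse_complement

log = logging.getLogger(__name__)

R_GAS = 1.987  # cal / (K mol)

# Unified nearest-neighbor parameters (SantaLucia 1998 / Allawi & SantaLucia
# 1997): propagation dH (kcal/mol), dS (cal/(K mol)) per dinucleotide duplex.
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# terminal initiation corrections
NN_INIT_AT = (2.3, 4.1)
NN_INIT_GC = (0.1, -2.8)
NN_SYM = (0.0, -1.4)


@dataclass(frozen=True)
class PCRConditions:
    monovalent_mM: float = 50.0
    primer_nM: float = 500.0


def melting_temperature(sequence: str, conditions: PCRConditions = PCRConditions()) -> float:
    """Nearest-neighbor duplex Tm in °C.

    ΔH/ΔS sums over dinucleotide steps plus terminal initiation terms; the
    monovalent-salt correction adds 0.368·(N−1)·ln[Mon+] to ΔS; Tm =
    1000·ΔH / (ΔS + R·ln CT) − 273.15 with CT the excess (primer) strand
    concentration.  Self-complementary sequences are detected and get the
    symmetry entropy term.
    """
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError("sequence too short for the nearest-neighbor model (< 8 nt)")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        inc = NN_INIT_AT if end in "AT" else NN_INIT_GC
        dh += inc[0]
        ds += inc[1]
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        ds += NN_SYM[1]
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in NN_PARAMS:
            pair = reverse_complement(pair)
        dh += NN_PARAMS[pair][0]
        ds += NN_PARAMS[pair][1]
    mon = conditions.monovalent_mM * 1e-3
    ds += 0.368 * (len(seq) - 1) * math.log(mon)
    k = conditions.primer_nM * 1e-9
    return (1000.0 * dh) / (ds + R_GAS * math.log(k)) - 273.15


# ---------------------------------------------------------------------------
# Candidate enumeration


@dataclass(frozen=True)
class PrimerConstraints:
    """Hard gates applied during sliding-window enumeration."""

    gc_min: float = 25.0
    gc_max: float = 75.0
    max_homopolymer: int = 4
    gc_clamp: bool = True  # 3'-terminal base must be G or C
    self_tail_len: int = 4  # reject when the 3' tail re-anneals within the primer


@dataclass(frozen=True)
class PrimerOptima:
    tm: float = 60.0
    gc: float = 50.0
    length: int = 20
    tm_sigma: float = 2.5
    gc_sigma: float = 10.0
    length_sigma: float = 2.0
    pair_tm_sigma: float = 2.0
    dimer_run: int = 8
    dimer_factor: float = 0.1


@dataclass(frozen=True)
class Primer:
    """A candidate primer; sequence is always written 5'->3'."""

    sequence: str
    contig: str
    start: int  # plus-strand window start
    strand: str
    tm: float
    gc: float
    weight: float
    region_role: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PrimerPair:
    forward: Primer
    reverse: Primer
    pair_weight: float = 0.0
    amplicon_by_state: dict = field(default_factory=dict)


@dataclass
class PrimerSet:
    """Role-labeled validation primers with their joint compatibility weight."""

    roles: dict[str, Primer]
    set_weight: float
    pair_weights: dict[tuple[str, str], float] = field(default_factory=dict)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def passes_constraints(seq: str, constraints: PrimerConstraints) -> bool:
    if not constraints.gc_min <= _gc_percent(seq) <= constraints.gc_max:
        return False
    if _max_homopolymer(seq) > constraints.max_homopolymer:
        return False
    if constraints.gc_clamp and seq[-1] not in "GC":
        return False
    if constraints.self_tail_len:
        tail = seq[-constraints.self_tail_len :]
        if reverse_complement(tail) in seq:
            return False
    if set(seq) - set("ACGT"):
        return False
    return True


def primer_weight(primer_or_seq, optima: PrimerOptima = PrimerOptima(),
                  conditions: PCRConditions = PCRConditions()) -> float:
    """Product of Gaussian penalty terms for Tm, GC and length; in (0, 1]."""
    if isinstance(primer_or_seq, Primer):
        tm, gc, length = primer_or_seq.tm, primer_or_seq.gc, primer_or_seq.length
    else:
        seq = primer_or_seq
        tm, gc, length = melting_temperature(seq, conditions), _gc_percent(seq), len(seq)
    w = math.exp(-((tm - optima.tm) ** 2) / (2 * optima.tm_sigma**2))
    w *= math.exp(-((gc - optima.gc) ** 2) / (2 * optima.gc_sigma**2))
    w *= math.exp(-((length - optima.length) ** 2) / (2 * optima.length_sigma**2))
    return w


def enumerate_primers(
    genome_state: GenomeState | Genome | str,
    region: tuple[str, int, int] | None,
    length_range: tuple[int, int] = (18, 28),
    constraints: PrimerConstraints = PrimerConstraints(),
    optima: PrimerOptima = PrimerOptima(),
    conditions: PCRConditions = PCRConditions(),
    strand: str | None = None,
    region_role: str = "",
) -> list[Primer]:
    """Every window of each allowed length, both strands, passing the gates.

    ``strand`` restricts output to forward ('+') or reverse ('-') primers;
    start coordinates are always plus-strand window starts.
    """
    if isinstance(genome_state, GenomeState):
        genome = genome_state.genome
    elif isinstance(genome_state, Genome):
        genome = genome_state
    else:
        genome = Genome({"seq": genome_state})
        if region is None:
            region = ("seq", 0, len(genome_state))
    contig, rstart, rend = region
    seq = genome.contigs[contig][rstart:rend]
    lo, hi = length_range
    out: list[Primer] = []
    for n in range(lo, hi + 1):
        for i in range(0, len(seq) - n + 1):
            window = seq[i : i + n]
            for st in "+-" if strand is None else strand:
                s = window if st == "+" else reverse_complement(window)
                if not passes_constraints(s, constraints):
                    continue
                tm = melting_temperature(s, conditions)
                out.append(
                    Primer(
                        sequence=s,
                        contig=contig,
                        start=rstart + i,
                        strand=st,
                        tm=tm,
                        gc=_gc_percent(s),
                        weight=0.0,
                        region_role=region_role,
                    )
                )
    out = [replace(p, weight=primer_weight(p, optima)) for p in out]
    out.sort(key=lambda p: (-p.weight, p.start, p.strand, p.length))
    return out


# ---------------------------------------------------------------------------
# Pair and set weighting


def _longest_cross_complement_run(a: str, b: str) -> int:
    """Longest run of ``a`` that is reverse-complementary to a run of ``b``."""
    target = reverse_complement(b)
    best = 0
    n, m = len(a), len(target)
    # classic O(n*m) longest-common-substring on small strings
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == target[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def pair_weight(forward: Primer, reverse: Primer, optima: PrimerOptima = PrimerOptima()) -> float:
    """Joint pair weight: product of primer weights, ΔTm penalty, dimer gate."""
    w = forward.weight * reverse.weight
    dt = forward.tm - reverse.tm
    w *= math.exp(-(dt**2) / (2 * optima.pair_tm_sigma**2))
    if _longest_cross_complement_run(forward.sequence, reverse.sequence) >= optima.dimer_run:
        w *= optima.dimer_factor
    return w


@dataclass(frozen=True)
class AnnealingParams:
    initial_temperature: float = 10.0
    cooling_rate: float = 0.995
    iterations: int = 20000


MANDATORY_ROLES = ("sF", "sR")

# (forward role, reverse role) amplicons whose compatibility the set weight
# aggregates; pairs whose roles are absent from a candidate map are skipped
DEFAULT_PAIR_SPECS = (
    ("sF", "sR"),
    ("sF", "oR_delta"),
    ("oF_delta", "sR"),
    ("sF", "oR_ab"),
    ("oF_ab", "sR"),
    ("iF_delta", "iR_delta"),
    ("iF_ab", "iR_ab"),
    ("AmpF", "AmpR"),
)


def set_weight_of(
    assignment: dict[str, Primer],
    pair_specs=DEFAULT_PAIR_SPECS,
    optima: PrimerOptima = PrimerOptima(),
    _cache: dict | None = None,
) -> tuple[float, dict]:
    """Product of pair weights over the applicable amplicons; 0 on conflicts."""
    seqs = [p.sequence for p in assignment.values()]
    if len(set(seqs)) != len(seqs):
        return 0.0, {}
    weight = 1.0
    pairs: dict[tuple[str, str], float] = {}
    for fr, rr in pair_specs:
        if fr not in assignment or rr not in assignment:
            continue
        f, r = assignment[fr], assignment[rr]
        key = (f.sequence, r.sequence)
        if _cache is not None and key in _cache:
            pw = _cache[key]
        else:
            pw = pair_weight(f, r, optima)
            if _cache is not None:
                _cache[key] = pw
        pairs[(fr, rr)] = pw
        weight *= pw
    return weight, pairs


def optimize_primer_set(
    candidates_by_role: dict[str, list[Primer]],
    pair_specs=DEFAULT_PAIR_SPECS,
    annealing_params: AnnealingParams = AnnealingParams(),
    seed: int = 0,
    optima: PrimerOptima = PrimerOptima(),
) -> PrimerSet:
    """Best-seen primer set under simulated annealing over role assignments.

    Mandatory roles (sF, sR) must have candidates; optional roles with
    empty candidate lists are dropped with a warning.  Deterministic given
    the seed; on instances small enough to enumerate, the result matches
    exhaustive search (a tested property).
    """
    for role in MANDATORY_ROLES:
        if not candidates_by_role.get(role):
            raise PrimerRoleError(f"mandatory primer role {role!r} has no candidates")
    roles = {}
    for role, cands in candidates_by_role.items():
        if cands:
            roles[role] = list(cands)
        else:
            log.warning("primer role %s has no candidates; dropped from the set", role)
    rng = np.random.default_rng(seed)
    role_names = sorted(roles)
    state = {r: 0 for r in role_names}
    cache: dict = {}

    def weight_of(st):
        return set_weight_of(
            {r: roles[r][i] for r, i in st.items()}, pair_specs, optima, cache
        )

    cur_w, _ = weight_of(state)
    best_state, best_w = dict(state), cur_w
    temp = annealing_params.initial_temperature
    for _ in range(annealing_params.iterations):
        role = role_names[int(rng.integers(len(role_names)))]
        proposal = dict(state)
        proposal[role] = int(rng.integers(len(roles[role])))
        new_w, _ = weight_of(proposal)
        if new_w >= cur_w or rng.random() < math.exp((new_w - cur_w) / max(temp, 1e-12)):
            state, cur_w = proposal, new_w
            if cur_w > best_w:
                best_state, best_w = dict(state), cur_w
        temp *= annealing_params.cooling_rate
    assignment = {r: roles[r][i] for r, i in best_state.items()}
    w, pairs = set_weight_of(assignment, pair_specs, optima, cache)
    return PrimerSet(roles=assignment, set_weight=w, pair_weights=pairs)


def exhaustive_primer_set(
    candidates_by_role: dict[str, list[Primer]],
    pair_specs=DEFAULT_PAIR_SPECS,
    optima: PrimerOptima = PrimerOptima(),
) -> PrimerSet:
    """Exhaustive-enumeration optimum; oracle for small instances."""
    import itertools

    roles = {r: c for r, c in candidates_by_role.items() if c}
    names = sorted(roles)
    best, best_w, best_pairs = None, -1.0, {}
    for combo in itertools.product(*(range(len(roles[r])) for r in names)):
        assignment = {r: roles[r][i] for r, i in zip(names, combo)}
        w, pairs = set_weight_of(assignment, pair_specs, optima)
        if w > best_w:
            best, best_w, best_pairs = assignment, w, pairs
    return PrimerSet(roles=best, set_weight=best_w, pair_weights=best_pairs)


# ---------------------------------------------------------------------------
# In-silico PCR


def _find_sites(template: str, primer: str, tolerance: int) -> list[int]:
    """Start positions where the primer anneals on the template's + strand.

    At tolerance 0 matching is exact; otherwise up to ``tolerance``
    substitutions are allowed in the 5' part while the 3'-terminal 3 nt
    must match exactly.
    """
    n, m = len(template), len(primer)
    if m > n:
        return []
    if tolerance == 0:
        out, i = [], template.find(primer)
        while i != -1:
            out.append(i)
            i = template.find(primer, i + 1)
        return out
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = win != p
    ok = (mism.sum(axis=1) <= tolerance) & (~mism[:, -3:].any(axis=1))
    return [int(i) for i in np.flatnonzero(ok)]


def insilico_pcr(
    template,
    forward,
    reverse,
    max_amplicon: int = 5000,
    mismatch_tolerance: int = 0,
) -> list[int]:
    """Predicted amplicon lengths for a primer pair on a template.

    ``template`` may be a sequence, Genome, or GenomeState.  A product
    forms when one primer matches the + strand and the other's reverse
    complement lies downstream with non-overlapping sites, within
    ``max_amplicon``; length spans both primer outer coordinates.
    """
    fseq = forward.sequence if isinstance(forward, Primer) else str(forward)
    rseq = reverse.sequence if isinstance(reverse, Primer) else str(reverse)
    if isinstance(template, GenomeState):
        contigs = template.genome.contigs.values()
    elif isinstance(template, Genome):
        contigs = template.contigs.values()
    else:
        contigs = [str(template)]
    lengths: list[int] = []
    orientations = [(fseq, rseq)] if fseq == rseq else [(fseq, rseq), (rseq, fseq)]
    for seq in contigs:
        for left, right in orientations:
            f_sites = _find_sites(seq, left, mismatch_tolerance)
            r_sites = _find_sites(seq, reverse_complement(right), mismatch_tolerance)
            for i in f_sites:
                f_end = i + len(left)
                for j in r_sites:
                    r_end = j + len(right)
                    if j >= f_end and r_end - i <= max_amplicon:
                        lengths.append(r_end - i)
    return sorted(lengths)


def cpcr_decision_table(
    primer_set: PrimerSet,
    states: dict[str, GenomeState],
    max_amplicon: int = 5000,
    pair_specs=DEFAULT_PAIR_SPECS,
):
    """Predicted colony-PCR presence/length per primer pair and genome state.

    Returns a DataFrame with one row per (pair, state) and a verdict on
    whether the sF/sR pattern discriminates the three genotypes: either it
    amplifies only the knock-out (delta) state under the size cap, or it
    amplifies all states with pairwise-distinct lengths (small-feature
    regime, resolved by band migration).
    """
    import pandas as pd

    rows = []
    sfsr: dict[str, list[int]] = {}
    for fr, rr in pair_specs:
        if fr not in primer_set.roles or rr not in primer_set.roles:
            continue
        f, r = primer_set.roles[fr], primer_set.roles[rr]
        for label, state in states.items():
            lengths = insilico_pcr(state, f, r, max_amplicon)
            rows.append(
                {
                    "pair": f"{fr}/{rr}",
                    "state": label,
                    "present": bool(lengths),
                    "lengths": ",".join(map(str, lengths)),
                }
            )
            if (fr, rr) == ("sF", "sR"):
                sfsr[label] = lengths
    df = pd.DataFrame(rows)
    verdict = "not_discriminating"
    if sfsr:
        present = {s for s, ls in sfsr.items() if ls}
        if present == {"delta"}:
            verdict = "delta_only"
        elif present == set(states):
            firsts = [tuple(ls) for ls in sfsr.values()]
            if len(set(firsts)) == len(firsts):
                verdict = "distinct_lengths"
    df.attrs["sf_sr_verdict"] = verdict
    return df
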