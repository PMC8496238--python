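"""Donor DNA construction for both editing steps.

Step one knocks out the (expanded) feature: the donor carries homology arms
flanking the expanded bounds around an engineered landing-pad insert — a
nuclease target that exists nowhere in the genome within a configurable
Hamming margin, so the second cut is genome-unique.  Step two adds the
locus back: the payload is the original expanded interval with the feature
either restored verbatim or substituted, so a wild-type add-back donor is a
literal substring of the reference genome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ArmError, UniqueInsertError
from .genome import Feature, Genome
from .motif import IUPAC, Segment, TargetMotif
from .scoring import QCThresholds, gc_percent, polyt_score
from .targets import OffTargetIndex

ARM_LENGTH_DEFAULT = 50
ARM_LENGTH_FLOOR = 20


@dataclass(frozen=True)
class DonorDNA:
    """Homology-arm + payload construct for step one or step two."""

    us_arm: str
    payload: str
    ds_arm: str
    step: str  # "one" | "two"
    source_coords: tuple  # (contig, (us_start, us_end), (ds_start, ds_end))
    payload_kind: str  # "generated_target" | "user_insert" | "addback_feature"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.us_arm or not self.ds_arm:
            raise ArmError("homology arms must be nonempty")

    @property
    def sequence(self) -> str:
        return self.us_arm + self.payload + self.ds_arm

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Landing-pad generation


def _sample_motif_instance(motif: TargetMotif, rng: np.random.Generator) -> tuple[str, str]:
    """One concrete (spacer, pam) drawn uniformly per ambiguity code."""

    def draw(segments: tuple[Segment, ...]) -> str:
        out = []
        for seg in segments:
            n = int(rng.integers(seg.min_count, seg.max_count + 1))
            bases = IUPAC[seg.code]
            out.extend(bases[int(i)] for i in rng.integers(0, len(bases), size=n))
        return "".join(out)

    return draw(motif.spacer_segments), draw(motif.pam_segments)


def assemble_site(motif: TargetMotif, spacer: str, pam: str) -> str:
    """Genomic-orientation sequence of a spacer+PAM site."""
    return spacer + pam if motif.pam_side == "three_prime" else pam + spacer


def generate_unique_target(
    genome: Genome,
    motif: TargetMotif,
    thresholds: QCThresholds = QCThresholds(),
    min_genome_distance: int = 6,
    rng_seed: int = 0,
    max_attempts: int = 1000,
    index: OffTargetIndex | None = None,
) -> str:
    """A landing-pad site (spacer+PAM) absent from the genome.

    Rejection-samples motif instances until one passes the polyT/GC gates
    and its spacer has at least ``min_genome_distance`` mismatches to every
    motif-compatible window on both strands.  Deterministic given the seed.
    """
    if min_genome_distance < 1:
        raise ValueError("min_genome_distance must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if index is None:
        index = OffTargetIndex(genome, motif)
    for _ in range(max_attempts):
        spacer, pam = _sample_motif_instance(motif, rng)
        if polyt_score(spacer) > thresholds.polyt_max:
            continue
        if not thresholds.gc_min <= gc_percent(spacer) <= thresholds.gc_max:
            continue
        if index.min_distance(spacer) < min_genome_distance:
            continue
        return assemble_site(motif, spacer, pam)
    raise UniqueInsertError(
        f"no unique insert found after {max_attempts} attempts "
        f"(min_genome_distance={min_genome_distance})"
    )


# ---------------------------------------------------------------------------
# Donor assembly


def _count_occurrences(haystack: str, needle: str) -> int:
    count, i = 0, haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


def _check_arm_unique(genome: Genome, contig: str, arm: str, label: str) -> None:
    """Arms must occur exactly once per haplotype of the locus, nowhere else."""
    group = set(genome.group_of(contig))
    for cname, seq in genome.contigs.items():
        n = _count_occurrences(seq, arm)
        if cname == contig and n != 1:
            raise ArmError(f"{label} arm occurs {n} times in {cname} (expected exactly 1)")
        if cname not in group and n != 0:
            raise ArmError(f"{label} arm also occurs in unrelated contig {cname}")


def _extract_arms(
    genome: Genome, feature: Feature, arm_length: int
) -> tuple[str, str, tuple, tuple]:
    if arm_length < ARM_LENGTH_FLOOR:
        raise ValueError(f"arm_length must be >= {ARM_LENGTH_FLOOR}")
    seq = genome.contigs[feature.contig]
    es, ee = feature.expanded_start, feature.expanded_end
    if es - arm_length < 0:
        raise ArmError(f"upstream arm runs off the start of {feature.contig}")
    if ee + arm_length > len(seq):
        raise ArmError(f"downstream arm runs off the end of {feature.contig}")
    us_iv = (es - arm_length, es)
    ds_iv = (ee, ee + arm_length)
    us_arm = seq[us_iv[0] : us_iv[1]]
    ds_arm = seq[ds_iv[0] : ds_iv[1]]
    _check_arm_unique(genome, feature.contig, us_arm, "upstream")
    _check_arm_unique(genome, feature.contig, ds_arm, "downstream")
    return us_arm, ds_arm, us_iv, ds_iv


def build_step1_donor(
    genome: Genome,
    expanded_feature: Feature,
    insert: str,
    arm_length: int = ARM_LENGTH_DEFAULT,
    payload_kind: str = "generated_target",
) -> DonorDNA:
    """Knock-out donor: arms flanking the expanded feature around the insert."""
    us_arm, ds_arm, us_iv, ds_iv = _extract_arms(genome, expanded_feature, arm_length)
    return DonorDNA(
        us_arm=us_arm,
        payload=insert,
        ds_arm=ds_arm,
        step="one",
        source_coords=(expanded_feature.contig, us_iv, ds_iv),
        payload_kind=payload_kind,
        label=f"{expanded_feature.name}:step1",
    )


_IUPAC_SET = set(IUPAC)


def build_step2_donor(
    genome: Genome,
    expanded_feature: Feature,
    replacement: str | None = None,
    arm_length: int = ARM_LENGTH_DEFAULT,
    label: str | None = None,
) -> DonorDNA:
    """Add-back donor restoring the expanded interval.

    ``replacement`` substitutes exactly the original feature interval; when
    None the wild-type sequence is restored, making the donor a substring
    of the + genome (amplifiable from wild-type DNA).
    """
    if replacement is not None and (set(replacement) - _IUPAC_SET):
        raise ValueError("replacement contains non-IUPAC characters")
    us_arm, ds_arm, us_iv, ds_iv = _extract_arms(genome, expanded_feature, arm_length)
    seq = genome.contigs[expanded_feature.contig]
    f = expanded_feature
    payload = (
        seq[f.expanded_start : f.start]
        + (replacement if replacement is not None else seq[f.start : f.end])
        + seq[f.end : f.expanded_end]
    )
    return DonorDNA(
        us_arm=us_arm,
        payload=payload,
        ds_arm=ds_arm,
        step="two",
        source_coords=(f.contig, us_iv, ds_iv),
        payload_kind="addback_feature",
        label=label or f"{f.name}:step2" + (":wt" if replacement is None else ":edited"),
    )


def combinatorial_donors(
    genome: Genome,
    expanded_feature: Feature,
    site_edits: list[tuple[tuple[int, int], str]],
    arm_length: int = ARM_LENGTH_DEFAULT,
) -> list[DonorDNA]:
    """One add-back donor per subset of site edits (2^k), labeled by bitmask.

    Each edit is ``((start, end), replacement)`` in genomic coordinates
    inside the expanded feature; intervals must be disjoint.  Bitmask order
    follows the site order given; bit i set means site i carries its edited
    sequence.  The intervening sequence is never touched.
    """
    f = expanded_feature
    sites = sorted(enumerate(site_edits), key=lambda e: e[1][0][0])
    prev_end = f.expanded_start
    for _, ((s, e), _rep) in sites:
        if s < prev_end:
            raise ValueError("site edit intervals overlap or fall outside the expanded feature")
        if e > f.expanded_end:
            raise ValueError("site edit interval extends beyond the expanded feature")
        prev_end = e
    us_arm, ds_arm, us_iv, ds_iv = _extract_arms(genome, f, arm_length)
    seq = genome.contigs[f.contig]
    k = len(site_edits)
    donors = []
    for bits in itertools.product((0, 1), repeat=k):
        parts, cursor = [], f.expanded_start
        for orig_idx, ((s, e), rep) in sites:
            parts.append(seq[cursor:s])
            parts.append(rep if bits[orig_idx] else seq[s:e])
            cursor = e
        parts.append(seq[cursor : f.expanded_end])
        mask = "".join(str(b) for b in bits)
        donors.append(
            DonorDNA(
                us_arm=us_arm,
                payload="".join(parts),
                ds_arm=ds_arm,
                step="two",
                source_coords=(f.contig, us_iv, ds_iv),
                payload_kind="addback_feature",
                label=f"{f.name}:AB{mask}",
            )
        )
    return donors
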