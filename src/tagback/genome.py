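"""Genome and feature bookkeeping plus simulated homology-directed repair.

Coordinates are 0-based half-open everywhere inside the package; GFF3's
1-based closed convention is converted at the I/O boundary.  The HDR model
is exact and seamless: the interval between the donor's two homology-arm
anchor points is replaced by the donor payload on every haplotype contig of
the locus's ploidy group (homozygous-edit model).  A consequence the model
makes testable is loss of heterozygosity: allelic variants inside the
replaced interval are overwritten by the single donor allele.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, IntegrationError

_VALID = set("ACGTN")


@dataclass
class Genome:
    """Named contigs, optionally grouped into haplotype sets of one locus."""

    contigs: dict[str, str]
    ploidy_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                raise FormatError(f"contig {name!r} contains non-ACGTN characters {sorted(bad)}")

    def group_of(self, contig: str) -> list[str]:
        """Haplotype contigs representing the same locus as ``contig``."""
        for members in self.ploidy_groups.values():
            if contig in members:
                return list(members)
        return [contig]

    def copy(self) -> "Genome":
        return Genome(dict(self.contigs), {k: list(v) for k, v in self.ploidy_groups.items()})

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class Feature:
    """A genomic interval selected for editing, with expansion bookkeeping."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    name: str = "feature"
    expanded_start: int | None = None
    expanded_end: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise FormatError(f"feature {self.name}: invalid interval [{self.start},{self.end})")
        if self.expanded_start is None:
            self.expanded_start = self.start
        if self.expanded_end is None:
            self.expanded_end = self.end
        if self.expanded_start > self.start or self.expanded_end < self.end:
            raise FormatError(f"feature {self.name}: expanded bounds must contain the feature")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def expanded_length(self) -> int:
        return self.expanded_end - self.expanded_start

    def with_expansion(self, expanded_start: int, expanded_end: int) -> "Feature":
        return dataclasses.replace(self, expanded_start=expanded_start, expanded_end=expanded_end)


@dataclass(frozen=True)
class EditRecord:
    contig: str
    removed_start: int
    removed_end: int
    inserted_sequence: str


@dataclass
class GenomeState:
    """One of the +, delta (knock-out) or addback sequence states of a genome."""

    label: str  # "plus" | "delta" | "addback"
    genome: Genome
    edit_log: list[EditRecord] = field(default_factory=list)

    def replay_from(self, reference: Genome) -> Genome:
        """Re-apply the edit log to ``reference``; must reproduce this state."""
        contigs = dict(reference.contigs)
        for rec in self.edit_log:
            seq = contigs[rec.contig]
            contigs[rec.contig] = (
                seq[: rec.removed_start] + rec.inserted_sequence + seq[rec.removed_end :]
            )
        return Genome(contigs, reference.ploidy_groups)


# ---------------------------------------------------------------------------
# FASTA / GFF3 / feature literals


def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly wrapped) FASTA file into a Genome, uppercased."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in contigs:
            raise FormatError(f"duplicate FASTA record name {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {name!r}")
        contigs[name] = seq
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _parse_literal(literal: str, genome: Genome | None) -> Feature:
    # "contig:start-end" or "contig:start-end:strand", 0-based half-open
    parts = literal.split(":")
    if len(parts) not in (2, 3):
        raise FormatError(f"bad feature literal {literal!r}; expected contig:start-end[:strand]")
    contig, span = parts[0], parts[1]
    strand = parts[2] if len(parts) == 3 else "+"
    if strand not in "+-":
        raise FormatError(f"bad strand {strand!r} in {literal!r}")
    try:
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"bad coordinates in {literal!r}") from exc
    feat = Feature(contig=contig, start=start, end=end, strand=strand, name=literal)
    _check_bounds(feat, genome)
    return feat


def _check_bounds(feat: Feature, genome: Genome | None) -> None:
    if genome is None:
        return
    if feat.contig not in genome.contigs:
        raise FormatError(f"feature {feat.name!r} on unknown contig {feat.contig!r}")
    if feat.end > len(genome.contigs[feat.contig]):
        raise FormatError(
            f"feature {feat.name!r} end {feat.end} beyond contig length "
            f"{len(genome.contigs[feat.contig])}"
        )


def read_features(path_or_literal: str | Path, genome: Genome | None = None) -> list[Feature]:
    """Features from a GFF3 file or from ``contig:start-end[:strand]`` literals.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open;
    literals are taken as already 0-based half-open.  A comma-separated
    string of literals yields one feature each.
    """
    text = str(path_or_literal)
    if Path(text).is_file():
        return _read_gff3(Path(text), genome)
    feats = [_parse_literal(lit.strip(), genome) for lit in text.split(",") if lit.strip()]
    if not feats:
        raise FormatError(f"no features in {path_or_literal!r}")
    return feats


def _read_gff3(path: Path, genome: Genome | None) -> list[Feature]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    feats: list[Feature] = []
    for rec in db.all_features(order_by=("seqid", "start")):
        name = rec.attributes.get("ID", rec.attributes.get("Name", [rec.featuretype]))[0]
        feat = Feature(
            contig=rec.seqid,
            start=rec.start - 1,  # 1-based closed -> 0-based half-open
            end=rec.end,
            strand=rec.strand if rec.strand in "+-" else "+",
            name=name,
        )
        _check_bounds(feat, genome)
        feats.append(feat)
    if not feats:
        raise FormatError(f"no feature lines in {path}")
    return feats


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\ttagback\tregion\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.name}\n"
            )


# ---------------------------------------------------------------------------
# Simulated HDR


def _find_occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _approximate_anchor(contig_seq: str, arm: str, max_mismatch_fraction: float) -> list[int]:
    """Unique best approximate occurrence of ``arm`` (substitutions only).

    Used when a haplotype carries variants inside an arm designed from its
    sister haplotype; the tolerance mirrors the arm-polymorphism cap.
    """
    n, m = len(contig_seq), len(arm)
    if m > n:
        return []
    seq = np.frombuffer(contig_seq.encode(), dtype=np.uint8)
    armv = np.frombuffer(arm.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    dists = (windows != armv).sum(axis=1)
    cap = int(max_mismatch_fraction * m)
    best = int(dists.min())
    if best > cap:
        return []
    return [int(i) for i in np.flatnonzero(dists == best)]


def _anchor_arm(
    contig_seq: str, arm: str, label: str, allow_approximate: bool, max_mismatch_fraction: float
) -> int:
    hits = _find_occurrences(contig_seq, arm)
    if len(hits) > 1:
        raise IntegrationError(f"{label} homology arm occurs {len(hits)} times in contig")
    if len(hits) == 1:
        return hits[0]
    if allow_approximate:
        hits = _approximate_anchor(contig_seq, arm, max_mismatch_fraction)
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise IntegrationError(f"{label} homology arm ambiguous (ties at best distance)")
    raise IntegrationError(f"{label} homology arm not found in contig")


def apply_hdr(
    state: GenomeState,
    donor,
    *,
    arm_mismatch_fraction: float = 0.05,
) -> GenomeState:
    """Integrate a donor by arm-anchored replacement; returns the next state.

    All haplotype contigs grouped with the donor's locus are edited (the
    homozygous-edit model).  On a haplotype where an arm does not match
    exactly, a unique best approximate anchor within
    ``arm_mismatch_fraction`` substitutions is accepted; ambiguity or
    absence is an :class:`IntegrationError`.
    """
    genome = state.genome.copy()
    log = list(state.edit_log)
    contig_names = genome.group_of(donor.source_coords[0])
    for cname in contig_names:
        seq = genome.contigs[cname]
        exact_only = len(contig_names) == 1
        us = _anchor_arm(seq, donor.us_arm, "upstream", not exact_only, arm_mismatch_fraction)
        ds = _anchor_arm(seq, donor.ds_arm, "downstream", not exact_only, arm_mismatch_fraction)
        us_end = us + len(donor.us_arm)
        if us_end > ds:
            raise IntegrationError(
                f"arms out of order on {cname}: upstream arm ends at {us_end}, "
                f"downstream arm begins at {ds}"
            )
        genome.contigs[cname] = seq[:us_end] + donor.payload + seq[ds:]
        log.append(EditRecord(cname, us_end, ds, donor.payload))
    next_label = {"one": "delta", "two": "addback"}.get(getattr(donor, "step", ""), "edited")
    return GenomeState(label=next_label, genome=genome, edit_log=log)


def write_edit_log(state: GenomeState, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tremoved_start\tremoved_end\tinserted_length\n")
        for rec in state.edit_log:
            fh.write(
                f"{rec.contig}\t{rec.removed_start}\t{rec.removed_end}\t"
                f"{len(rec.inserted_sequence)}\n"
            )
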