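"""Seeded synthetic-genome generation for fixtures and benchmarks.

Emulates a small fungal-like assembly: random sequence at a chosen GC
fraction, features planted verbatim at known positions, optional decoy
near-matches of a spacer (for off-target tests), and an optional second
haplotype carrying heterozygous SNVs at a chosen per-site rate.  SNVs are
kept outside an exclusion radius around planted features so that a locus
designed from one haplotype integrates and restores exactly on both; the
radius can be set to 0 to study loss of heterozygosity instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import Feature, Genome, write_fasta, write_gff3

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome."""

    length: int = 20000
    gc_fraction: float = 0.38  # A/T-rich, fungal-intergenic-like
    n_haplotypes: int = 1
    snv_rate: float = 0.0
    planted_features: list[tuple[int, str]] = field(default_factory=list)  # (pos, seq)
    planted_decoys: list[tuple[str, int]] = field(default_factory=list)  # (site_seq, n_mm)
    seed: int = 0
    contig_name: str = "chr1"
    snv_exclusion_radius: int = 3000

    def __post_init__(self) -> None:
        if self.n_haplotypes not in (1, 2):
            raise ValueError("n_haplotypes must be 1 or 2")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0,1]")


@dataclass
class SyntheticGenome:
    genome: Genome
    features: list[Feature]
    manifest: list[dict]

    def write(self, outdir: str | Path, stem: str = "synthetic") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / f"{stem}.fasta",
            "gff3": outdir / f"{stem}.gff3",
            "manifest": outdir / f"{stem}.manifest.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gff3(self.features, paths["gff3"])
        with open(paths["manifest"], "w") as fh:
            fh.write("kind\tcontig\tstart\tend\tsequence\tnote\n")
            for row in self.manifest:
                fh.write(
                    "\t".join(
                        str(row.get(k, "")) for k in ("kind", "contig", "start", "end",
                                                      "sequence", "note")
                    )
                    + "\n"
                )
        return paths


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=length, p=p)]


def _mutate(site: str, n_mm: int, rng: np.random.Generator) -> str:
    """Substitute n_mm distinct positions of a planted decoy."""
    seq = list(site)
    idxs = rng.choice(len(seq), size=n_mm, replace=False)
    for i in idxs:
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[int(i)] = choices[int(rng.integers(3))]
    return "".join(seq)


def generate_synthetic_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Deterministic genome + feature annotations + truth manifest."""
    rng = np.random.default_rng(spec.seed)
    arr = _random_sequence(rng, spec.length, spec.gc_fraction)
    manifest: list[dict] = []
    occupied: list[tuple[int, int]] = []
    hap_a = spec.contig_name if spec.n_haplotypes == 1 else f"{spec.contig_name}_hapA"

    def plant(pos: int, seq: str, kind: str, note: str = "") -> None:
        end = pos + len(seq)
        if pos < 0 or end > spec.length:
            raise ValueError(f"planted element [{pos},{end}) exceeds genome length")
        for s, e in occupied:
            if pos < e and end > s:
                raise ValueError(f"planted element [{pos},{end}) overlaps [{s},{e})")
        occupied.append((pos, end))
        arr[pos:end] = np.frombuffer(seq.encode(), dtype=np.uint8)
        manifest.append(
            {"kind": kind, "contig": hap_a, "start": pos, "end": end,
             "sequence": seq, "note": note}
        )

    features: list[Feature] = []
    for i, (pos, seq) in enumerate(spec.planted_features):
        plant(pos, seq.upper(), "feature", f"planted_feature_{i}")
        features.append(
            Feature(contig=hap_a, start=pos, end=pos + len(seq), name=f"planted_feature_{i}")
        )
    for i, (site, n_mm) in enumerate(spec.planted_decoys):
        mutated = _mutate(site.upper(), n_mm, rng)
        # place uniformly in free space; bounded retries keep determinism
        for _ in range(200):
            pos = int(rng.integers(0, spec.length - len(mutated)))
            if all(pos >= e or pos + len(mutated) <= s for s, e in occupied):
                break
        else:
            raise ValueError("could not place decoy without overlap")
        plant(pos, mutated, "decoy", f"decoy_{i}_mm{n_mm}")

    seq_a = arr.tobytes().decode()
    if spec.n_haplotypes == 1:
        genome = Genome({hap_a: seq_a})
        return SyntheticGenome(genome, features, manifest)

    # second haplotype: SNVs outside the exclusion radius of planted elements
    hap_b = f"{spec.contig_name}_hapB"
    excluded = np.zeros(spec.length, dtype=bool)
    for s, e in occupied:
        lo = max(0, s - spec.snv_exclusion_radius)
        hi = min(spec.length, e + spec.snv_exclusion_radius)
        excluded[lo:hi] = True
    arr_b = arr.copy()
    snv_mask = (rng.random(spec.length) < spec.snv_rate) & ~excluded
    for i in np.flatnonzero(snv_mask):
        cur = chr(arr_b[i])
        choices = [b for b in "ACGT" if b != cur]
        arr_b[i] = ord(choices[int(rng.integers(3))])
        manifest.append(
            {"kind": "snv", "contig": hap_b, "start": int(i), "end": int(i) + 1,
             "sequence": chr(arr_b[i]), "note": f"ref={cur}"}
        )
    genome = Genome(
        {hap_a: seq_a, hap_b: arr_b.tobytes().decode()},
        ploidy_groups={spec.contig_name: [hap_a, hap_b]},
    )
    return SyntheticGenome(genome, features, manifest)
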