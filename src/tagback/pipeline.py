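"""End-to-end design pipeline: scan -> QC -> expand -> donors -> primers -> cPCR.

The pipeline is a pure function of (genome, feature, config): one global
seed fans out to per-stage child seeds by stable hashing, so reruns are
byte-identical and individual stages are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import DesignConfig, stage_seed
from .donors import DonorDNA, build_step1_donor, build_step2_donor, generate_unique_target
from .genome import Feature, Genome, GenomeState, apply_hdr, write_edit_log, write_fasta
from .motif import parse_motif
from .primers import (
    cpcr_decision_table,
    enumerate_primers,
    insilico_pcr,
    optimize_primer_set,
)
from .scoring import ONTARGET_SURROGATE_NOTE
from .targets import (
    CandidateTarget,
    OffTargetIndex,
    expand_feature,
    passing_targets,
    rank_targets,
)


@dataclass
class DesignResult:
    feature: Feature
    targets: list[CandidateTarget]
    chosen_target: CandidateTarget
    insert: str
    step1_donor: DonorDNA
    step2_donor: DonorDNA
    states: dict[str, GenomeState]
    primer_set: object
    cpcr_table: pd.DataFrame
    config: DesignConfig
    notes: list[str] = field(default_factory=list)


def run_design(
    genome: Genome,
    feature: Feature,
    config: DesignConfig = DesignConfig(),
    replacement: str | None = None,
) -> DesignResult:
    """Run the full two-step design for one feature.

    ``replacement`` substitutes the feature interval in the add-back donor;
    None restores the wild-type sequence.
    """
    notes = [ONTARGET_SURROGATE_NOTE] if config.ontarget_scorer == "surrogate" else []
    motif = parse_motif(config.motif)
    index = OffTargetIndex(genome, motif)

    expanded = expand_feature(
        genome,
        feature,
        motif,
        config.thresholds,
        max_expansion=config.max_expansion,
        step=config.expansion_step,
        index=index,
        ontarget_scorer=config.ontarget_scorer,
    )
    candidates = passing_targets(
        genome,
        motif,
        config.thresholds,
        region=expanded,
        index=index,
        ontarget_scorer=config.ontarget_scorer,
    )
    inside = [t for t in candidates if t.start >= expanded.expanded_start
              and t.end <= expanded.expanded_end]
    ranked = rank_targets(inside, expanded)
    chosen = next(t for t in ranked if t.passes_qc)

    insert = generate_unique_target(
        genome,
        motif,
        config.thresholds,
        min_genome_distance=config.min_genome_distance,
        rng_seed=stage_seed(config.rng_seed, "unique_target"),
        index=index,
    )

    step1 = build_step1_donor(genome, expanded, insert, config.arm_length)
    step2 = build_step2_donor(genome, expanded, replacement, config.arm_length)

    plus = GenomeState(label="plus", genome=genome)
    delta = apply_hdr(plus, step1)
    addback = apply_hdr(delta, step2)
    states = {"plus": plus, "delta": delta, "addback": addback}

    primer_set, dropped = design_validation_primers(
        plus, delta, addback, expanded, step1, step2, config
    )
    for role in dropped:
        notes.append(f"primer role {role} dropped: region too short for usable candidates")
    cpcr = cpcr_decision_table(primer_set, states, config.max_amplicon)

    return DesignResult(
        feature=expanded,
        targets=ranked,
        chosen_target=chosen,
        insert=insert,
        step1_donor=step1,
        step2_donor=step2,
        states=states,
        primer_set=primer_set,
        cpcr_table=cpcr,
        config=config,
        notes=notes,
    )


def design_validation_primers(
    plus: GenomeState,
    delta: GenomeState,
    addback: GenomeState,
    expanded: Feature,
    step1: DonorDNA,
    step2: DonorDNA,
    config: DesignConfig,
):
    """Enumerate role-specific candidates and anneal them into one set.

    Roles: sF/sR flank the locus in sequence shared by all three states;
    oF/oR anneal inside the state-specific region (the landing pad for
    delta, the restored region for AB) to pair across junctions with sF/sR;
    iF/iR lie wholly inside the insert or the restored feature; AmpF/AmpR
    sit at the ends of the step-2 donor so it can be amplified from
    wild-type DNA.  Optional roles without candidates are dropped.
    """
    genome = plus.genome
    contig = expanded.contig
    seq_len = len(genome.contigs[contig])
    es, ee = expanded.expanded_start, expanded.expanded_end
    arm = config.arm_length
    span = config.outer_span

    def enum(state, region, strand, role):
        c, s, e = region
        s, e = max(0, s), min(len(state.genome.contigs[c]), e)
        if e - s < 18:
            return []
        return enumerate_primers(
            state, (c, s, e), constraints=config_constraints(config), strand=strand,
            region_role=role, optima=config.optima, conditions=config.pcr_conditions,
        )

    # delta-state coordinates of the landing-pad insert (first edit record)
    rec1 = delta.edit_log[0]
    ins_iv = (rec1.contig, rec1.removed_start, rec1.removed_start + len(step1.payload))
    # addback-state coordinates of the restored payload and of the feature
    rec2 = addback.edit_log[len(delta.edit_log)]
    pay_start = rec2.removed_start
    feat_off = expanded.start - expanded.expanded_start
    feat_len = len(step2.payload) - (expanded.expanded_length - expanded.length)
    ab_payload_iv = (rec2.contig, pay_start, pay_start + len(step2.payload))
    ab_feature_iv = (rec2.contig, pay_start + feat_off, pay_start + feat_off + feat_len)

    candidates = {
        "sF": enum(plus, (contig, es - arm - span, es), "+", "far_us"),
        "sR": enum(plus, (contig, ee, ee + arm + span), "-", "far_ds"),
        "oF_delta": enum(delta, ins_iv, "+", "insert_internal"),
        "oR_delta": enum(delta, ins_iv, "-", "insert_internal"),
        "iF_delta": enum(delta, ins_iv, "+", "insert_internal"),
        "iR_delta": enum(delta, ins_iv, "-", "insert_internal"),
        "oF_ab": enum(addback, ab_payload_iv, "+", "feature_internal"),
        "oR_ab": enum(addback, ab_payload_iv, "-", "feature_internal"),
        "iF_ab": enum(addback, ab_feature_iv, "+", "feature_internal"),
        "iR_ab": enum(addback, ab_feature_iv, "-", "feature_internal"),
        "AmpF": enum(plus, (contig, es - arm, es - arm + config.amp_window), "+", "arm_us"),
        "AmpR": enum(plus, (contig, ee + arm - config.amp_window, ee + arm), "-", "arm_ds"),
    }
    # keep annealing tractable: the best few dozen candidates per role
    candidates = {r: c[:40] for r, c in candidates.items()}
    dropped = [r for r, c in candidates.items() if not c and r not in ("sF", "sR")]
    primer_set = optimize_primer_set(
        {r: c for r, c in candidates.items() if c},
        annealing_params=config.annealing,
        seed=stage_seed(config.rng_seed, "primer_annealing"),
        optima=config.optima,
    )
    # an internal pair must actually amplify its own state; a region shorter
    # than two non-overlapping primers (e.g. a 23 nt landing pad) cannot
    infeasible = []
    for pair, state in ((("iF_delta", "iR_delta"), delta), (("iF_ab", "iR_ab"), addback)):
        fr, rr = pair
        if fr in primer_set.roles and rr in primer_set.roles:
            if not insilico_pcr(
                state, primer_set.roles[fr], primer_set.roles[rr], config.max_amplicon
            ):
                infeasible.extend(pair)
    if infeasible:
        remaining = {
            r: c for r, c in candidates.items() if c and r not in infeasible
        }
        primer_set = optimize_primer_set(
            remaining,
            annealing_params=config.annealing,
            seed=stage_seed(config.rng_seed, "primer_annealing"),
            optima=config.optima,
        )
        dropped = dropped + infeasible
    return primer_set, dropped


def config_constraints(config: DesignConfig):
    from .primers import PrimerConstraints

    return PrimerConstraints()


# ---------------------------------------------------------------------------
# Output bundle


def write_bundle(result: DesignResult, outdir: str | Path) -> dict[str, Path]:
    """Write the four result artifacts plus predicted genomes and logs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # (a) ranked targets: TSV + BED
    rows = []
    for t in result.targets:
        rows.append(
            {
                "contig": t.contig, "start": t.start, "end": t.end, "strand": t.strand,
                "spacer": t.spacer, "pam": t.pam, "cut_position": t.cut_position,
                **{k: v for k, v in t.metrics.items()},
                "passes_qc": t.passes_qc,
                "failure_reasons": ",".join(t.failure_reasons),
            }
        )
    paths["targets_tsv"] = outdir / "targets.tsv"
    pd.DataFrame(rows).to_csv(paths["targets_tsv"], sep="\t", index=False)
    paths["targets_bed"] = outdir / "targets.bed"
    with open(paths["targets_bed"], "w") as fh:
        for t in result.targets:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\ttarget\t0\t{t.strand}\n")

    # (b)+(c) donors as FASTA with structured headers + manifest
    paths["donors_fasta"] = outdir / "donors.fasta"
    with open(paths["donors_fasta"], "w") as fh:
        for d in (result.step1_donor, result.step2_donor):
            fh.write(
                f">{d.label} step={d.step} kind={d.payload_kind} "
                f"arms={len(d.us_arm)},{len(d.ds_arm)}\n{d.sequence}\n"
            )
    paths["donors_tsv"] = outdir / "donors.tsv"
    with open(paths["donors_tsv"], "w") as fh:
        fh.write("label\tstep\tpayload_kind\tus_arm_len\tpayload_len\tds_arm_len\n")
        for d in (result.step1_donor, result.step2_donor):
            fh.write(
                f"{d.label}\t{d.step}\t{d.payload_kind}\t{len(d.us_arm)}\t"
                f"{len(d.payload)}\t{len(d.ds_arm)}\n"
            )

    # (d) primers + cPCR decision table
    paths["primers_tsv"] = outdir / "primers.tsv"
    with open(paths["primers_tsv"], "w") as fh:
        fh.write("role\tsequence\tcontig\tstart\tstrand\ttm\tgc\tweight\n")
        for role, p in sorted(result.primer_set.roles.items()):
            fh.write(
                f"{role}\t{p.sequence}\t{p.contig}\t{p.start}\t{p.strand}\t"
                f"{p.tm:.2f}\t{p.gc:.1f}\t{p.weight:.4f}\n"
            )
    paths["cpcr_tsv"] = outdir / "cpcr.tsv"
    result.cpcr_table.to_csv(paths["cpcr_tsv"], sep="\t", index=False)

    # predicted genome states + edit log
    for label in ("delta", "addback"):
        p = outdir / f"genome_{label}.fasta"
        write_fasta(result.states[label].genome, p)
        paths[f"genome_{label}"] = p
    paths["edit_log"] = outdir / "edit_log.tsv"
    write_edit_log(result.states["addback"], paths["edit_log"])

    # machine-readable run manifest
    paths["manifest"] = outdir / "run_manifest.jsonl"
    with open(paths["manifest"], "w") as fh:
        fh.write(json.dumps({
            "feature": result.feature.name,
            "expanded_bounds": [result.feature.expanded_start, result.feature.expanded_end],
            "chosen_target": result.chosen_target.spacer + result.chosen_target.pam,
            "insert": result.insert,
            "set_weight": result.primer_set.set_weight,
            "cpcr_verdict": result.cpcr_table.attrs.get("sf_sr_verdict"),
            "notes": result.notes,
            "seed": result.config.rng_seed,
        }) + "\n")
    return paths
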