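"""Worked-example constants and ready-made demonstration loci.

The sequences are the published motifs of two well-characterized
Candida albicans transcription-factor binding sites and the engineered
landing-pad target used to edit them: Wor1 binds the 9 bp consensus
TTAAAGTTT (scrambled control ACCCTTGCG), Zap1 binds the 11-mer palindrome
ACCTTNAAGGT, and the landing pad is a 23 nt SpCas9 site (20 nt spacer +
TGG PAM).  They make handy fixtures because the A/T-rich binding sites
lack NGG PAMs and so exercise the feature-expansion path.
"""

from __future__ import annotations

from .genome import Feature
from .motif import parse_motif
from .synth import SyntheticGenome, SyntheticSpec, generate_synthetic_genome

CAS9_MOTIF = "N{17}|N{3}>NGG"
CAS12A_MOTIF = "TTTV<N{20}"

WOR1_SITE = "TTAAAGTTT"  # 9 bp Wor1 binding consensus
WOR1_SCRAMBLE = "ACCCTTGCG"  # scrambled control of the same length
ZAP1_SITE = "ACCTTNAAGGT"  # 11 bp Zap1 binding consensus
LANDING_PAD_SITE = "CGTACGCTGCAGGTCGACAGTGG"  # 20 nt spacer + TGG PAM
LANDING_PAD_SPACER = LANDING_PAD_SITE[:20]
LANDING_PAD_PAM = LANDING_PAD_SITE[20:]

# the demonstrated edit used a cut site 172 bp upstream of the 9 bp feature
WOR1_TARGET_OFFSET_UPSTREAM = 172


def cas9_motif():
    return parse_motif(CAS9_MOTIF)


def wor1_locus(
    length: int = 12000, seed: int = 7, feature_pos: int = 6000
) -> tuple[SyntheticGenome, Feature]:
    """A synthetic locus with a Wor1 site and a Cas9 site 172 bp upstream.

    The planted Cas9 site is the landing-pad sequence itself (it carries a
    canonical NGG PAM), standing in for the natural cut site used in the
    demonstrated edit; the A/T-rich Wor1 site itself contains no PAM.  The
    random background may of course contribute further targets of its own.
    """
    target_pos = feature_pos - WOR1_TARGET_OFFSET_UPSTREAM - len(LANDING_PAD_SITE)
    spec = SyntheticSpec(
        length=length,
        seed=seed,
        planted_features=[(target_pos, LANDING_PAD_SITE), (feature_pos, WOR1_SITE)],
    )
    sg = generate_synthetic_genome(spec)
    feature = next(f for f in sg.features if f.start == feature_pos)
    return sg, feature


def zap1_locus(
    length: int = 16000, seed: int = 11, first_pos: int = 7000, separation: int = 645
) -> tuple[SyntheticGenome, Feature, Feature]:
    """Two Zap1 sites 645 bp apart (edge-to-edge), for combinatorial edits."""
    site = ZAP1_SITE.replace("N", "A")  # one concrete instance of the motif
    second_pos = first_pos + len(site) + separation
    spec = SyntheticSpec(
        length=length,
        seed=seed,
        planted_features=[(first_pos, site), (second_pos, site)],
    )
    sg = generate_synthetic_genome(spec)
    return sg, sg.features[0], sg.features[1]
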