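"""RGN target-motif grammar.

A motif string describes the spacer and PAM of an RNA-guided nuclease in a
compact dialect: IUPAC nucleotide codes, ``{n}``/``{n,m}`` quantifiers,
``|`` cut marks inside the spacer, and a single ``>`` (3' PAM, right of the
spacer) or ``<`` (5' PAM, left of the spacer) separator.  ``N{17}|N{3}>NGG``
is SpCas9: a 20 nt spacer, blunt cut 3 nt from the PAM, NGG PAM.

Matching semantics: an assembly-gap ``N`` in the genome matches only the
motif code ``N``; every other code matches exactly its IUPAC base set.
Ranged quantifiers match as the union of their fixed-length expansions, not
greedily, so every window length is reported.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache

from .errors import MotifParseError

# IUPAC code -> set of concrete bases it stands for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _char_class(code: str) -> str:
    # genome 'N' pairs only with motif 'N' (conservative gap handling)
    bases = IUPAC[code]
    if code == "N":
        bases += "N"
    return bases if len(bases) == 1 else "[" + bases + "]"


@dataclass(frozen=True)
class Segment:
    """One motif segment: an IUPAC code with a count range."""

    code: str
    min_count: int
    max_count: int

    def serialize(self) -> str:
        if self.min_count == self.max_count:
            return self.code if self.min_count == 1 else f"{self.code}{{{self.min_count}}}"
        return f"{self.code}{{{self.min_count},{self.max_count}}}"


@dataclass(frozen=True)
class TargetMotif:
    """Parsed nuclease recognition motif."""

    raw: str
    spacer_segments: tuple[Segment, ...]
    pam_segments: tuple[Segment, ...]
    pam_side: str  # "five_prime" | "three_prime"
    # cut offsets in nt from the PAM-proximal spacer end (min-count arithmetic);
    # multiple marks are kept, only the PAM-proximal one is used downstream
    cut_offsets: tuple[int, ...] = ()
    # boundary indices of '|' marks in spacer_segments, for serialization
    cut_boundaries: tuple[int, ...] = field(default=(), repr=False)

    @property
    def cut_offset_sense(self) -> int | None:
        """PAM-proximal cut offset (blunt-cut model); None when no mark."""
        return min(self.cut_offsets) if self.cut_offsets else None

    @property
    def spacer_len_range(self) -> tuple[int, int]:
        return (
            sum(s.min_count for s in self.spacer_segments),
            sum(s.max_count for s in self.spacer_segments),
        )

    @property
    def pam_len_range(self) -> tuple[int, int]:
        return (
            sum(s.min_count for s in self.pam_segments),
            sum(s.max_count for s in self.pam_segments),
        )

    def serialize(self) -> str:
        """Canonical motif string; re-parses to an equal motif."""
        spacer = ""
        for i, seg in enumerate(self.spacer_segments):
            if i in self.cut_boundaries:
                spacer += "|"
            spacer += seg.serialize()
        if len(self.spacer_segments) in self.cut_boundaries:
            spacer += "|"
        pam = "".join(s.serialize() for s in self.pam_segments)
        if self.pam_side == "three_prime":
            return f"{spacer}>{pam}"
        return f"{pam}<{spacer}"

    # -- matching ----------------------------------------------------------

    def expansions(self) -> tuple["FixedMotif", ...]:
        return _expansions_for(self)

    def match_at(self, sequence: str, offset: int, strand: str = "+"):
        """Spacer/PAM decomposition of the window at ``offset``, or None.

        Minus-strand matching is performed against the reverse complement of
        the window; the returned spacer and PAM read 5'->3' on the spacer's
        sense strand.  When ranged quantifiers allow several window lengths
        the shortest matching expansion wins.
        """
        if not 0 <= offset <= len(sequence):
            raise IndexError(f"offset {offset} outside sequence of length {len(sequence)}")
        for fixed in self.expansions():
            window = sequence[offset : offset + fixed.total_len]
            if len(window) < fixed.total_len:
                continue
            probe = reverse_complement(window) if strand == "-" else window
            m = fixed.anchored.match(probe)
            if m:
                return fixed.decompose(probe)
        return None


@dataclass(frozen=True)
class FixedMotif:
    """A fully fixed-length expansion of a motif, compiled for scanning."""

    spacer_len: int
    pam_len: int
    pam_side: str
    scan: re.Pattern  # overlapping finditer via lookahead
    anchored: re.Pattern

    @property
    def total_len(self) -> int:
        return self.spacer_len + self.pam_len

    def decompose(self, window: str) -> tuple[str, str]:
        """Split a matching window into (spacer, pam)."""
        if self.pam_side == "three_prime":
            return window[: self.spacer_len], window[self.spacer_len :]
        return window[self.pam_len :], window[: self.pam_len]


def _expand_segments(segments: tuple[Segment, ...], cap: int = 4096):
    """All fixed-count assignments of ranged segments (cartesian product)."""
    choices = [range(s.min_count, s.max_count + 1) for s in segments]
    n = 1
    for c in choices:
        n *= len(c)
        if n > cap:
            raise MotifParseError("motif quantifier ranges expand to too many fixed forms")
    out = []
    for counts in itertools.product(*choices):
        out.append(tuple(zip((s.code for s in segments), counts)))
    return out


@lru_cache(maxsize=64)
def _expansions_for(motif: TargetMotif) -> tuple[FixedMotif, ...]:
    fixed = []
    for sp in _expand_segments(motif.spacer_segments):
        for pm in _expand_segments(motif.pam_segments):
            sp_pat = "".join(_char_class(c) * n for c, n in sp)
            pm_pat = "".join(_char_class(c) * n for c, n in pm)
            if motif.pam_side == "three_prime":
                body = sp_pat + pm_pat
            else:
                body = pm_pat + sp_pat
            fixed.append(
                FixedMotif(
                    spacer_len=sum(n for _, n in sp),
                    pam_len=sum(n for _, n in pm),
                    pam_side=motif.pam_side,
                    scan=re.compile(f"(?=({body}))"),
                    anchored=re.compile(body),
                )
            )
    # shortest first so match_at prefers the minimal window
    fixed.sort(key=lambda f: (f.total_len, f.spacer_len))
    return tuple(fixed)


_QUANT = re.compile(r"\{(\d+)(?:,(\d+))?\}")


def _parse_side(side: str, base_index: int) -> tuple[list[Segment], list[int]]:
    """Parse one side of the separator into segments plus cut-mark boundaries."""
    segments: list[Segment] = []
    cuts: list[int] = []
    i = 0
    while i < len(side):
        ch = side[i]
        if ch == "|":
            cuts.append(len(segments))
            i += 1
        elif ch in IUPAC:
            m = _QUANT.match(side, i + 1)
            if m:
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                if lo > hi or hi == 0:
                    raise MotifParseError(
                        f"malformed quantifier {m.group(0)!r} at index {base_index + i + 1}"
                    )
                segments.append(Segment(ch, lo, hi))
                i = m.end()
            else:
                if i + 1 < len(side) and side[i + 1] == "{":
                    raise MotifParseError(
                        f"malformed quantifier at index {base_index + i + 1}"
                    )
                segments.append(Segment(ch, 1, 1))
                i += 1
        else:
            raise MotifParseError(f"unknown symbol {ch!r} at index {base_index + i}")
    return segments, cuts


def _merge_fixed_runs(
    segments: list[Segment], cuts: list[int]
) -> tuple[tuple[Segment, ...], tuple[int, ...]]:
    """Collapse adjacent same-code fixed-count segments not split by a cut mark."""
    merged: list[Segment] = []
    new_cuts: list[int] = []
    cutset = set(cuts)
    for i, seg in enumerate(segments):
        if i in cutset:
            new_cuts.append(len(merged))
        last = merged[-1] if merged else None
        if (
            last is not None
            and i not in cutset
            and last.code == seg.code
            and last.min_count == last.max_count
            and seg.min_count == seg.max_count
        ):
            merged[-1] = Segment(last.code, last.min_count + seg.min_count,
                                 last.min_count + seg.min_count)
        else:
            merged.append(seg)
    if len(segments) in cutset:
        new_cuts.append(len(merged))
    return tuple(merged), tuple(new_cuts)


def parse_motif(motif_string: str) -> TargetMotif:
    """Parse a motif string such as ``N{17}|N{3}>NGG`` or ``TTTV<N{20}``."""
    s = motif_string.strip().upper()
    if not s:
        raise MotifParseError("empty motif string")
    n_sep = s.count(">") + s.count("<")
    if n_sep == 0:
        raise MotifParseError("motif has no PAM separator ('>' or '<')")
    if n_sep > 1:
        idx = max(s.rfind(">"), s.rfind("<"))
        raise MotifParseError(f"multiple PAM separators; extra {s[idx]!r} at index {idx}")

    if ">" in s:
        pam_side = "three_prime"
        spacer_str, pam_str = s.split(">")
        spacer_base, pam_base = 0, len(spacer_str) + 1
    else:
        pam_side = "five_prime"
        pam_str, spacer_str = s.split("<")
        pam_base, spacer_base = 0, len(pam_str) + 1

    spacer_segs, cuts = _parse_side(spacer_str, spacer_base)
    pam_segs, pam_cuts = _parse_side(pam_str, pam_base)
    if pam_cuts:
        raise MotifParseError("cut marks ('|') are only meaningful inside the spacer")
    if not spacer_segs:
        raise MotifParseError("motif has an empty spacer")
    if not pam_segs:
        raise MotifParseError("motif has an empty PAM")

    spacer_segs, cuts = _merge_fixed_runs(spacer_segs, cuts)
    pam_segs, _ = _merge_fixed_runs(pam_segs, [])

    # cut offsets in nt from the PAM-proximal spacer end, by min-count sums
    offsets = []
    for b in cuts:
        if pam_side == "three_prime":
            offsets.append(sum(seg.min_count for seg in spacer_segs[b:]))
        else:
            offsets.append(sum(seg.min_count for seg in spacer_segs[:b]))
    return TargetMotif(
        raw=motif_string,
        spacer_segments=spacer_segs,
        pam_segments=pam_segs,
        pam_side=pam_side,
        cut_offsets=tuple(offsets),
        cut_boundaries=tuple(cuts),
    )


def match_at(motif: TargetMotif, sequence: str, offset: int, strand: str = "+"):
    """Functional wrapper around :meth:`TargetMotif.match_at`."""
    return motif.match_at(sequence, offset, strand)
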