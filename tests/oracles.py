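"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles — character loops, naive
window enumeration, and a separate transcription of the published
off-target formula — deliberately sharing no code with the package so that
agreement is evidence, not tautology.
"""

from itertools import combinations

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T", "N"},
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def code_matches(code: str, base: str) -> bool:
    if base == "N":
        return code == "N"
    return base in IUPAC_SETS[code]


def pattern_matches(pattern: str, window: str) -> bool:
    """Fixed-length IUPAC pattern vs concrete window, position by position."""
    return len(pattern) == len(window) and all(
        code_matches(c, b) for c, b in zip(pattern, window)
    )


def naive_scan(sequence: str, spacer_pattern: str, pam_pattern: str, pam_side: str = "3p"):
    """All (start, strand, spacer, pam) windows matching spacer+PAM, both strands."""
    if pam_side == "3p":
        pattern = spacer_pattern + pam_pattern
    else:
        pattern = pam_pattern + spacer_pattern
    total = len(pattern)
    hits = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        n = len(seq)
        for i in range(n - total + 1):
            window = seq[i : i + total]
            if pattern_matches(pattern, window):
                if pam_side == "3p":
                    spacer, pam = window[: len(spacer_pattern)], window[len(spacer_pattern):]
                else:
                    spacer, pam = window[len(pam_pattern):], window[: len(pam_pattern)]
                start = i if strand == "+" else n - i - total
                hits.append((start, strand, spacer, pam))
    return sorted(hits)


def naive_offtargets(
    contigs: dict, spacer: str, pam_pattern: str, max_errors: int, pam_side: str = "3p"
):
    """All PAM-anchored windows within Hamming <= max_errors of the spacer.

    Returns (contig, window_start_plus, strand, mismatch_positions) with
    position 1 = PAM-distal end of the spacer.
    """
    L, P = len(spacer), len(pam_pattern)
    hits = []
    for cname, sequence in contigs.items():
        for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
            n = len(seq)
            for i in range(n - L - P + 1):
                if pam_side == "3p":
                    proto, pam = seq[i : i + L], seq[i + L : i + L + P]
                else:
                    pam, proto = seq[i : i + P], seq[i + P : i + P + L]
                if not pattern_matches(pam_pattern, pam):
                    continue
                mism = [k for k in range(L) if proto[k] != spacer[k]]
                if len(mism) > max_errors:
                    continue
                if pam_side == "3p":
                    positions = tuple(k + 1 for k in mism)
                else:
                    positions = tuple(sorted(L - k for k in mism))
                start = i if strand == "+" else n - i - L - P
                hits.append((cname, start, strand, positions))
    return sorted(hits)


# Independent transcription of the Hsu et al. 2013 per-hit formula.
HSU_W = [
    0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
]


def hsu_single_oracle(positions, spacer_len=20):
    n = len(positions)
    if n == 0:
        return 100.0
    term1 = 1.0
    for p in positions:
        idx = p - 1 + (20 - spacer_len)
        w = HSU_W[idx] if idx >= 0 else 0.0
        term1 *= 1.0 - w
    if n == 1:
        return 100.0 * term1
    pairs = list(combinations(sorted(positions), 2))
    d = sum(b - a for a, b in pairs) / len(pairs)
    return 100.0 * term1 * (1.0 / (((19.0 - d) / 19.0) * 4.0 + 1.0)) * (1.0 / n**2)


def naive_primer_windows(region: str, length_range, gc_bounds, max_homopolymer,
                         need_gc_clamp=True, self_tail=4):
    """Sliding-window primer enumeration under the package's hard gates."""
    out = []
    lo, hi = length_range
    for n in range(lo, hi + 1):
        for i in range(len(region) - n + 1):
            for strand in "+-":
                s = region[i : i + n] if strand == "+" else revcomp(region[i : i + n])
                gc = 100.0 * (s.count("G") + s.count("C")) / n
                if not gc_bounds[0] <= gc <= gc_bounds[1]:
                    continue
                run = 1
                best = 1
                for a, b in zip(s, s[1:]):
                    run = run + 1 if a == b else 1
                    best = max(best, run)
                if best > max_homopolymer:
                    continue
                if need_gc_clamp and s[-1] not in "GC":
                    continue
                if self_tail and revcomp(s[-self_tail:]) in s:
                    continue
                out.append((i, strand, s))
    return sorted(out)


def naive_pcr(template: str, fwd: str, rev: str, max_amplicon: int):
    """All product lengths from exact full-length primer sites, both roles."""
    lengths = []
    pairs = [(fwd, rev)] if fwd == rev else [(fwd, rev), (rev, fwd)]
    for left, right in pairs:
        f_sites = [i for i in range(len(template) - len(left) + 1)
                   if template[i : i + len(left)] == left]
        rc = revcomp(right)
        r_sites = [j for j in range(len(template) - len(rc) + 1)
                   if template[j : j + len(rc)] == rc]
        for i in f_sites:
            for j in r_sites:
                if j >= i + len(left) and j + len(rc) - i <= max_amplicon:
                    lengths.append(j + len(rc) - i)
    return sorted(lengths)
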