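"""In-silico 16S rDNA screening by PCR amplicon extraction and RFLP.

Models the computational half of a restriction-profile screen of a
clone library: find the near-full-length 16S rDNA amplicon delimited by
the universal primers 27F/1492R, digest it with HhaI (GCG^C), and call
a clone positive when its fragment profile differs from the host
(vector-strain) control profile — difference from the host indicates an
insert-borne 16S gene.

PCR is modelled as IUPAC-degeneracy-aware site-pair finding with a
bounded mismatch count and a 3'-clamp (no mismatch in the final three
3' bases); no thermodynamics. Gel comparison is modelled as fragment-
length matching with a fractional tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import SequenceRecord, reverse_complement

# IUPAC nucleotide -> 4-bit base set (A=1, C=2, G=4, T=8)
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

PRIMER_27F = "AGAGTTTGATCCTGGCTCAG"
PRIMER_1492R = "GGTTACCTTGTTACGACTT"

HHAI_SITE = "GCGC"
HHAI_CUT_OFFSET = 3  # GCG^C


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    name: str = "27F/1492R"
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 10:
                raise ValueError(f"primer {p!r} shorter than 10 bases")
            bad = set(p.upper()) - set(_IUPAC_BITS)
            if bad:
                raise ValueError(f"primer {p!r}: invalid characters {sorted(bad)}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


DEFAULT_PRIMERS = PrimerPair(PRIMER_27F, PRIMER_1492R)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product; start/end are 1-based inclusive template
    coordinates spanning both primer sites, sequence oriented from the
    forward primer."""

    seq_id: str
    start: int
    end: int
    sequence: str
    strand: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestProfile:
    """Restriction fragment lengths of one amplicon, sorted descending."""

    amplicon_id: str
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(l < 1 for l in self.fragment_lengths):
            raise ValueError("fragment lengths must be >= 1")

    @property
    def total_length(self) -> int:
        return sum(self.fragment_lengths)


@dataclass(frozen=True)
class ProfileComparison:
    query_id: str
    control_id: str
    matched: bool
    unmatched_fragments: tuple[tuple[int, str], ...]


@dataclass
class ScreenResult:
    verdict: str  # positive | negative | no_amplicon
    amplicons: list[Amplicon] = field(default_factory=list)
    profiles: list[DigestProfile] = field(default_factory=list)
    comparisons: list[ProfileComparison] = field(default_factory=list)


def _bits(seq: str) -> np.ndarray:
    return np.array([_IUPAC_BITS[c] for c in seq.upper()], dtype=np.uint8)


def _match_positions(
    template_bits: np.ndarray,
    site: str,
    max_mismatch: int,
    clamp: tuple[int, ...] = (),
) -> np.ndarray:
    """0-based start positions where ``site`` matches the template with at
    most ``max_mismatch`` mismatches and none at the ``clamp`` offsets."""
    sbits = _bits(site)
    m = len(template_bits) - len(sbits) + 1
    if m <= 0:
        return np.array([], dtype=int)
    mismatches = np.zeros(m, dtype=np.int32)
    clamp_ok = np.ones(m, dtype=bool)
    for j, pb in enumerate(sbits):
        hit = (template_bits[j : j + m] & pb) != 0
        mismatches += ~hit
        if j in clamp:
            clamp_ok &= hit
    return np.where((mismatches <= max_mismatch) & clamp_ok)[0]


def find_amplicon(
    record: SequenceRecord,
    primers: PrimerPair = DEFAULT_PRIMERS,
    min_len: int = 1200,
    max_len: int = 1700,
) -> list[Amplicon]:
    """Find all primer-delimited amplicons on either strand.

    The forward primer is matched directly; the reverse primer is matched
    as its reverse complement downstream on the same template strand.
    Mismatches are forbidden in the three 3'-terminal primer bases.
    Returns an empty list when no site pair lies within the length bounds.
    """
    fwd = primers.forward.upper().replace("U", "T")
    rev_site = reverse_complement(primers.reverse)
    fwd_clamp = tuple(range(len(fwd) - 3, len(fwd)))
    # the 3' end of the reverse primer maps to the *first* bases of its
    # reverse-complement site on the template
    rev_clamp = (0, 1, 2)
    amplicons: list[Amplicon] = []
    L = len(record.seq)
    for strand, template in (("+", record.seq), ("-", reverse_complement(record.seq))):
        tbits = _bits(template)
        f_hits = _match_positions(tbits, fwd, primers.max_mismatch, fwd_clamp)
        r_hits = _match_positions(tbits, rev_site, primers.max_mismatch, rev_clamp)
        for i in f_hits:
            for j in r_hits:
                end0 = j + len(rev_site)  # exclusive
                length = end0 - i
                if j <= i or not (min_len <= length <= max_len):
                    continue
                if strand == "+":
                    start, end = i + 1, end0
                else:
                    start, end = L - end0 + 1, L - i
                amplicons.append(
                    Amplicon(
                        seq_id=record.id,
                        start=start,
                        end=end,
                        sequence=template[i:end0],
                        strand=strand,
                    )
                )
    return amplicons


def digest(
    seq: str,
    site: str = HHAI_SITE,
    cut_offset: int = HHAI_CUT_OFFSET,
    amplicon_id: str = "",
) -> DigestProfile:
    """In-silico restriction digest.

    A cut is placed after ``cut_offset`` bases of every occurrence of the
    recognition site; overlapping occurrences each produce a cut.
    Fragment lengths are returned sorted descending and always sum to the
    input length.
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    site = site.upper()
    if set(site) - set("ACGT"):
        raise ValueError(f"recognition site {site!r} must be non-degenerate A/C/G/T")
    if not (0 <= cut_offset <= len(site)):
        raise ValueError(f"cut_offset must be within [0, {len(site)}]")
    seq = seq.upper()
    cuts: set[int] = set()
    pos = seq.find(site)
    while pos != -1:
        cut = pos + cut_offset
        if 0 < cut < len(seq):
            cuts.add(cut)
        pos = seq.find(site, pos + 1)
    bounds = [0, *sorted(cuts), len(seq)]
    fragments = sorted(
        (b - a for a, b in zip(bounds, bounds[1:])), reverse=True
    )
    return DigestProfile(amplicon_id=amplicon_id, fragment_lengths=tuple(fragments))


def compare_profiles(
    query: DigestProfile, control: DigestProfile, tolerance_frac: float = 0.05
) -> ProfileComparison:
    """Compare two fragment profiles at a fractional length tolerance.

    Fragments are paired by closest length (optimal one-to-one
    assignment); a pair is admissible when the length difference is at
    most ``tolerance_frac`` times the larger of the two. The profiles
    match iff every fragment of both pairs up — a proxy for two lanes
    looking identical on a 1% agarose gel.
    """
    if not query.fragment_lengths or not control.fragment_lengths:
        raise ValueError("profiles must be non-empty")
    if not (0 <= tolerance_frac < 1):
        raise ValueError("tolerance_frac must be in [0, 1)")
    q = np.array(query.fragment_lengths, dtype=float)
    c = np.array(control.fragment_lengths, dtype=float)
    diff = np.abs(q[:, None] - c[None, :])
    limit = tolerance_frac * np.maximum(q[:, None], c[None, :])
    big = 1e12
    cost = np.where(diff <= limit, diff, big)
    # pad to square so every fragment may stay unmatched
    n = max(len(q), len(c))
    padded = np.full((n, n), big)
    padded[: len(q), : len(c)] = cost
    rows, cols = linear_sum_assignment(padded)
    q_matched = np.zeros(len(q), dtype=bool)
    c_matched = np.zeros(len(c), dtype=bool)
    for r_i, c_i in zip(rows, cols):
        if r_i < len(q) and c_i < len(c) and padded[r_i, c_i] < big:
            q_matched[r_i] = True
            c_matched[c_i] = True
    unmatched = [(int(l), "query") for l, ok in zip(q, q_matched) if not ok]
    unmatched += [(int(l), "control") for l, ok in zip(c, c_matched) if not ok]
    return ProfileComparison(
        query_id=query.amplicon_id,
        control_id=control.amplicon_id,
        matched=not unmatched,
        unmatched_fragments=tuple(unmatched),
    )


def screen_clone(
    record: SequenceRecord,
    primers: PrimerPair = DEFAULT_PRIMERS,
    control: DigestProfile | None = None,
    site: str = HHAI_SITE,
    cut_offset: int = HHAI_CUT_OFFSET,
    tolerance_frac: float = 0.05,
    min_len: int = 1200,
    max_len: int = 1700,
) -> ScreenResult:
    """Screen one clone: positive iff some amplicon's digest profile
    differs from the host control profile (candidate insert-borne 16S);
    negative iff every amplicon matches the control; no_amplicon when the
    primers find nothing."""
    if control is None:
        raise ValueError("a host control DigestProfile is required")
    amplicons = find_amplicon(record, primers, min_len, max_len)
    if not amplicons:
        return ScreenResult(verdict="no_amplicon")
    profiles = [
        digest(a.sequence, site, cut_offset, amplicon_id=f"{a.seq_id}:{a.start}-{a.end}")
        for a in amplicons
    ]
    comparisons = [compare_profiles(p, control, tolerance_frac) for p in profiles]
    verdict = "positive" if any(not c.matched for c in comparisons) else "negative"
    return ScreenResult(
        verdict=verdict, amplicons=amplicons, profiles=profiles, comparisons=comparisons
    )
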