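"""Synthetic genome-fragment generator with truth bookkeeping.

Emulates the compositional structure the scanning analysis assumes: a
host backbone sampled from one 3rd-order Markov model, optionally with
an implanted segment sampled from a different model (a lateral-transfer
mimic), an rRNA-like block copied from a packaged synthetic 16S-like
reference, and non-overlapping fake ORF annotations covering a requested
coding fraction per region.

Because the window statistic measures deviation from a window-internal
maximal-order Markov expectation (built from tri- and di-nucleotide
counts), a generating model needs genuine 3rd-order dependence for
windows of the same source to share a reproducible signature; the
``sharpness`` parameter controls how strongly transition rows differ
across trinucleotide contexts (0 gives an i.i.d. sequence with no
signature). Defaults are chosen so a homogeneous fragment scores a high
mean internal correlation and a fragment with a divergent implant scores
a visibly lower one, bracketing the stable/unstable contrast the scanner
is meant to expose.

Every operation is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import FeatureInterval, SequenceRecord, reverse_complement
from .rflp import PRIMER_1492R, PRIMER_27F

_BASES = "ACGT"

# Default study conditions: host-like backbone at 48% GC, exogenous
# implant at 60% GC, 10 kb implant in a 30 kb fragment. The host model
# carries enough 3rd-order structure for a reproducible within-genome
# signature while its window z-scores stay near the calibrated regime;
# the implant is less self-coherent (an exogenous segment is typically
# compositionally heterogeneous), which is also what makes its windows
# correlate poorly with everything.
DEFAULT_HOST_GC = 48.0
DEFAULT_IMPLANT_GC = 60.0
DEFAULT_SHARPNESS = 0.7
DEFAULT_IMPLANT_SHARPNESS = 0.35
DEFAULT_LENGTH = 30_000
DEFAULT_IMPLANT_START = 10_001
DEFAULT_IMPLANT_LENGTH = 10_000

#: Minimum and maximum synthetic ORF length (bp).
ORF_MIN, ORF_MAX = 300, 2000


@dataclass
class MarkovModel3:
    """3rd-order Markov model: P(next base | preceding trinucleotide).

    ``probs`` has shape (64, 4); row order follows the canonical A<C<G<T
    trinucleotide index.
    """

    probs: np.ndarray
    label: str = "model"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (64, 4):
            raise ValueError("transition table must have shape (64, 4)")
        if (self.probs < 0).any():
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each context row must sum to 1")

    def stationary_context(self) -> np.ndarray:
        """Stationary distribution over the 64 trinucleotide contexts."""
        pi = np.full(64, 1.0 / 64)
        nxt = ((np.arange(64) & 15) << 2)
        for _ in range(500):
            new = np.zeros(64)
            for b in range(4):
                np.add.at(new, nxt + b, pi * self.probs[:, b])
            if np.abs(new - pi).sum() < 1e-13:
                pi = new
                break
            pi = new
        return pi

    def stationary_gc(self) -> float:
        """Exact stationary G+C percentage of the chain."""
        pi = self.stationary_context()
        base = pi @ self.probs
        return 100.0 * (base[1] + base[2])

    def stationary_tetra(self) -> np.ndarray:
        """Stationary tetranucleotide distribution (256 probabilities)."""
        pi = self.stationary_context()
        tet = np.zeros(256)
        for ctx in range(64):
            for b in range(4):
                tet[ctx * 4 + b] = pi[ctx] * self.probs[ctx, b]
        return tet


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a synthetic fragment bit-exactly
    and to evaluate calls against the known implant."""

    seq_id: str
    length: int
    host_model: str
    implant_model: str | None = None
    implant_start: int | None = None
    implant_end: int | None = None
    rrna_start: int | None = None
    rrna_end: int | None = None
    cds_intervals: list[FeatureInterval] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["cds_intervals"] = [
            {"seq_id": iv.seq_id, "start": iv.start, "end": iv.end, "kind": iv.kind, "label": iv.label}
            for iv in self.cds_intervals
        ]
        return json.dumps(d, indent=2)


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def make_model(
    gc_target: float, sharpness: float = DEFAULT_SHARPNESS, seed: int = 0, label: str | None = None
) -> MarkovModel3:
    """Draw a random 3rd-order Markov model with a prescribed stationary GC.

    Context-specific transition rows are softmax(log base + sharpness *
    noise); a scalar tilt on the G/C logits is then calibrated against
    the exact stationary distribution until the stationary GC is within
    0.1 percentage points of ``gc_target``. sharpness = 0 yields the
    i.i.d. limit (all rows equal to the base composition).
    """
    if not (0.0 < gc_target < 100.0):
        raise ValueError(f"gc_target must be in (0, 100), got {gc_target}")
    if sharpness < 0:
        raise ValueError("sharpness must be >= 0")
    g = gc_target / 100.0
    base = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    rng = np.random.default_rng(seed)
    logits = np.log(base)[None, :] + sharpness * rng.standard_normal((64, 4))
    gc_mask = np.array([0.0, 1.0, 1.0, 0.0])
    delta = 0.0
    model = MarkovModel3(_softmax(logits), label=label or f"gc{gc_target:g}_s{sharpness:g}_{seed}")
    for _ in range(60):
        model.probs = _softmax(logits + delta * gc_mask)
        gc = model.stationary_gc()
        if abs(gc - gc_target) < 0.1:
            break
        delta += (gc_target - gc) / 25.0
    return model


def _sample_chain(
    model: MarkovModel3, n: int, rng: np.random.Generator, state: int | None = None
) -> tuple[str, int]:
    """Sample ``n`` bases from the chain; returns (sequence, final state).

    ``state`` is the trinucleotide context index; when None, it is drawn
    from the model's stationary context distribution (a re-seeded
    junction).
    """
    if state is None:
        pi = model.stationary_context()
        state = int(rng.choice(64, p=pi / pi.sum()))
    cum = model.probs.cumsum(axis=1)
    us = rng.random(n)
    out = np.empty(n, dtype=np.uint8)
    for i in range(n):
        row = cum[state]
        b = int(np.searchsorted(row, us[i], side="right"))
        b = min(b, 3)
        out[i] = b
        state = ((state & 15) << 2) | b
    return "".join(_BASES[b] for b in out), state


# ---------------------------------------------------------------------------
# packaged synthetic 16S-like reference (not a real accession)

_PSEUDO_16S_CACHE: str | None = None
#: Offsets (0-based) at which GCGC sites are spliced into the reference.
PSEUDO_16S_SITE_OFFSETS = (220, 640, 1080)


def pseudo_16s() -> str:
    """A fixed packaged 16S-like reference sequence (synthetic).

    Deterministically generated: exact 27F site at the 5' end, exact
    1492R site (reverse-complemented) at the 3' end, a Markov-sampled
    core, and GCGC (HhaI) sites spliced in at known offsets so the digest
    profile is reproducible. It is a stand-in constructed for testing, not
    a real rRNA gene.
    """
    global _PSEUDO_16S_CACHE
    if _PSEUDO_16S_CACHE is None:
        rng = np.random.default_rng(1616)
        model = make_model(55.0, sharpness=0.8, seed=1616, label="pseudo16s")
        core_len = 1500 - len(PRIMER_27F) - len(PRIMER_1492R)
        core, _ = _sample_chain(model, core_len, rng)
        core = list(core)
        # remove incidental GCGC sites, then splice fixed ones
        s = "".join(core)
        while "GCGC" in s:
            i = s.index("GCGC")
            core[i + 1] = "A"
            s = "".join(core)
        for off in PSEUDO_16S_SITE_OFFSETS:
            core[off : off + 4] = "GCGC"
        _PSEUDO_16S_CACHE = PRIMER_27F + "".join(core) + reverse_complement(PRIMER_1492R)
    return _PSEUDO_16S_CACHE


def pseudo_16s_variant() -> str:
    """The packaged reference with one HhaI site moved — a divergent-16S
    fixture whose RFLP profile differs from the host control."""
    ref = pseudo_16s()
    first = len(PRIMER_27F) + PSEUDO_16S_SITE_OFFSETS[0]
    # destroy the first site and create one ~200 bp downstream
    moved = ref[:first] + "GAAC" + ref[first + 4 :]
    new_pos = first + 200
    return moved[:new_pos] + "GCGC" + moved[new_pos + 4 :]


# ---------------------------------------------------------------------------


def simulate_fragment(
    length: int = DEFAULT_LENGTH,
    host: MarkovModel3 | None = None,
    implant: tuple[MarkovModel3, int, int] | None = None,
    rrna: tuple[int, int] | None = None,
    seed: int = 0,
    seq_id: str | None = None,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Simulate a genome fragment with optional implant and rRNA block.

    ``implant`` is (model, start, implant_length) with a 1-based start;
    the implant's Markov context is re-seeded at the junction and the
    host chain resumes naturally from the implant's trailing context.
    ``rrna`` is (start, block_length); the block is copied verbatim from
    the packaged 16S-like reference and must not overlap the implant.
    """
    if length < 10:
        raise ValueError("fragment length must be >= 10")
    host = host or make_model(DEFAULT_HOST_GC, seed=101, label="host")
    seq_id = seq_id or f"sim{seed}"
    rng = np.random.default_rng(seed)

    blocks: list[tuple[int, int]] = []
    if implant is not None:
        imodel, istart, ilen = implant
        iend = istart + ilen - 1
        if not (1 <= istart <= iend <= length):
            raise ValueError(f"implant [{istart}, {iend}] outside fragment [1, {length}]")
        blocks.append((istart, iend))
    if rrna is not None:
        rstart, rlen = rrna
        rend = rstart + rlen - 1
        ref = pseudo_16s()
        if rlen > len(ref):
            raise ValueError(f"rRNA block length {rlen} exceeds reference length {len(ref)}")
        if not (1 <= rstart <= rend <= length):
            raise ValueError(f"rRNA block [{rstart}, {rend}] outside fragment [1, {length}]")
        if implant is not None and rstart <= blocks[0][1] and blocks[0][0] <= rend:
            raise ValueError("implant and rRNA blocks overlap")

    parts: list[str] = []
    pos = 1
    state: int | None = None
    if implant is not None:
        imodel, istart, ilen = implant
        if istart > 1:
            part, state = _sample_chain(host, istart - 1, rng, state)
            parts.append(part)
        part, state = _sample_chain(imodel, ilen, rng, None)  # re-seeded junction
        parts.append(part)
        pos = istart + ilen
    if pos <= length:
        part, state = _sample_chain(host, length - pos + 1, rng, state)
        parts.append(part)
    seq = "".join(parts)

    if rrna is not None:
        rstart, rlen = rrna
        seq = seq[: rstart - 1] + pseudo_16s()[:rlen] + seq[rstart - 1 + rlen :]

    record = SequenceRecord(id=seq_id, seq=seq, description="synthetic fragment", source="synthetic")
    truth = SyntheticTruth(
        seq_id=seq_id,
        length=length,
        host_model=host.label,
        implant_model=implant[0].label if implant is not None else None,
        implant_start=implant[1] if implant is not None else None,
        implant_end=implant[1] + implant[2] - 1 if implant is not None else None,
        rrna_start=rrna[0] if rrna is not None else None,
        rrna_end=rrna[0] + rrna[1] - 1 if rrna is not None else None,
        seed=seed,
    )
    return record, truth


def _fill_segment(
    rng: np.random.Generator, seg_start: int, seg_len: int, frac: float, seq_id: str, tag: str
) -> list[FeatureInterval]:
    """Place non-overlapping ORF intervals covering ~frac of a segment."""
    target = int(round(frac * seg_len))
    if target == 0 or target < ORF_MIN or seg_len < ORF_MIN:
        return []
    lengths: list[int] = []
    total = 0
    while total < target:
        l = int(rng.integers(ORF_MIN, ORF_MAX + 1))
        lengths.append(l)
        total += l
    overshoot = total - target
    for i in range(len(lengths) - 1, -1, -1):
        take = min(lengths[i] - ORF_MIN, overshoot)
        lengths[i] -= take
        overshoot -= take
        if overshoot == 0:
            break
    if overshoot > 0 and len(lengths) > 1:
        lengths.pop()  # all at minimum; accept a small undershoot
    total = sum(lengths)
    if total > seg_len:
        return []
    gaps = rng.multinomial(seg_len - total, np.full(len(lengths) + 1, 1.0 / (len(lengths) + 1)))
    intervals = []
    pos = seg_start + int(gaps[0])
    for i, l in enumerate(lengths):
        intervals.append(
            FeatureInterval(seq_id=seq_id, start=pos, end=pos + l - 1, kind="CDS", label=f"{tag}_orf{i+1:03d}")
        )
        pos += l + int(gaps[i + 1])
    return intervals


def make_cds_annotation(
    truth: SyntheticTruth,
    host_coding_frac: float = 0.65,
    implant_coding_frac: float = 0.40,
    seed: int = 0,
) -> list[FeatureInterval]:
    """Generate fake non-overlapping ORF intervals per region.

    The host backbone (excluding implant and rRNA blocks) and the implant
    each receive coverage close to the requested fraction; ORF lengths
    are uniform on [300, 2000] bp. Also recorded on ``truth``.
    """
    for name, frac in (("host_coding_frac", host_coding_frac), ("implant_coding_frac", implant_coding_frac)):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    excluded: list[tuple[int, int]] = []
    if truth.implant_start is not None:
        excluded.append((truth.implant_start, truth.implant_end))
    if truth.rrna_start is not None:
        excluded.append((truth.rrna_start, truth.rrna_end))
    excluded.sort()
    host_segments: list[tuple[int, int]] = []
    pos = 1
    for s, e in excluded:
        if s > pos:
            host_segments.append((pos, s - 1))
        pos = e + 1
    if pos <= truth.length:
        host_segments.append((pos, truth.length))

    intervals: list[FeatureInterval] = []
    host_total = sum(e - s + 1 for s, e in host_segments)
    if host_coding_frac > 0 and host_total > 0 and host_coding_frac * host_total < ORF_MIN:
        raise ValueError("host coding fraction infeasible given the 300 bp minimum ORF length")
    for k, (s, e) in enumerate(host_segments):
        intervals.extend(_fill_segment(rng, s, e - s + 1, host_coding_frac, truth.seq_id, f"h{k}"))
    if truth.implant_start is not None and implant_coding_frac > 0:
        ilen = truth.implant_end - truth.implant_start + 1
        if implant_coding_frac * ilen < ORF_MIN:
            raise ValueError("implant coding fraction infeasible given the 300 bp minimum ORF length")
        intervals.extend(
            _fill_segment(rng, truth.implant_start, ilen, implant_coding_frac, truth.seq_id, "i")
        )
    intervals.sort(key=lambda iv: iv.start)
    truth.cds_intervals = intervals
    return intervals
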