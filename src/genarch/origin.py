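"""Replication-origin architecture: windowed GC statistics and oriC calling.

On bacterial chromosomes the leading strand is G-rich, so the GC skew
(G-C)/(G+C) changes sign at the replication origin and terminus.  The
cumulative skew curve is minimal at oriC (where the sign flips from - to +
walking clockwise) and maximal at the terminus; both are reported at window
midpoints.  The DnaA initiator protein binds a 9-mer box (consensus
TTATCCACA) clustered near oriC, located here by a Hamming scan of both
strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import Feature, SeqRecord, revcomp

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class SkewProfile:
    """Per-window compositional statistic along a replicon."""

    window: int
    step: int
    starts: np.ndarray          # window start coordinates
    values: np.ndarray          # per-window statistic
    cumulative: np.ndarray      # running sum of values
    kind: str                   # "skew" or "gc_deviation"
    replicon_length: int = 0
    circular: bool = True

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.window // 2) % max(self.replicon_length, 1)


@dataclass
class OriginCall:
    """Called oriC/terminus plus any DnaA boxes found near the origin."""

    oriC: int | None
    terminus: int | None
    boxes: list = field(default_factory=list)
    notes: str = ""

    @property
    def found(self) -> bool:
        return self.oriC is not None


def _window_counts(seq: str, window: int, step: int, circular: bool):
    """Per-window counts of each base, honoring circular wrap."""
    L = len(seq)
    if window > L:
        raise ValueError(f"window {window} exceeds replicon length {L}")
    if window < 10 or step < 1:
        raise ValueError("window must be >= 10 and step >= 1")
    if circular:
        starts = np.arange(0, L, step)
        padded = seq + seq[: window - 1 + step]
    else:
        starts = np.arange(0, L - window + 1, step)
        padded = seq
    enc = _encode(padded)
    # prefix sums per base letter
    counts = {}
    for base, ch in (("A", b"A"), ("C", b"C"), ("G", b"G"), ("T", b"T")):
        mask = (enc == ch[0]).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(mask)])
        counts[base] = csum[starts + window] - csum[starts]
    return starts, counts


def gc_skew_profile(
    record: SeqRecord, window: int = 1000, step: int | None = None
) -> SkewProfile:
    """Windowed GC skew (G-C)/(G+C); windows with no G or C score 0."""
    if step is None:
        step = window
    circular = record.topology == "circular"
    starts, counts = _window_counts(record.sequence, window, step, circular)
    g = counts["G"].astype(float)
    c = counts["C"].astype(float)
    denom = g + c
    values = np.divide(g - c, denom, out=np.zeros_like(g), where=denom > 0)
    return SkewProfile(
        window=window, step=step, starts=starts, values=values,
        cumulative=np.cumsum(values), kind="skew",
        replicon_length=record.length, circular=circular,
    )


def gc_deviation_profile(record: SeqRecord, window: int = 1000,
                         step: int | None = None) -> SkewProfile:
    """Windowed GC percent minus the whole-replicon GC percent."""
    if step is None:
        step = window
    circular = record.topology == "circular"
    starts, counts = _window_counts(record.sequence, window, step, circular)
    g, c = counts["G"].astype(float), counts["C"].astype(float)
    a, t = counts["A"].astype(float), counts["T"].astype(float)
    denom = a + c + g + t
    win_gc = 100.0 * np.divide(g + c, denom, out=np.zeros_like(g), where=denom > 0)
    seq = record.sequence
    n_unambig = record.length - seq.count("N")
    mean_gc = 100.0 * (seq.count("G") + seq.count("C")) / max(n_unambig, 1)
    return SkewProfile(
        window=window, step=step, starts=starts, values=win_gc - mean_gc,
        cumulative=np.cumsum(win_gc - mean_gc), kind="gc_deviation",
        replicon_length=record.length, circular=circular,
    )


def call_origin(profile: SkewProfile, flat_tolerance: float = 1.0) -> OriginCall:
    """Locate oriC (global minimum of cumulative skew) and terminus (maximum).

    A near-flat cumulative curve (range below ``flat_tolerance``, in summed
    per-window skew units) yields a no-transition result rather than an
    arbitrary coordinate.
    """
    if profile.kind != "skew":
        raise ValueError("call_origin requires a GC-skew profile")
    if not profile.circular:
        return OriginCall(None, None, notes="linear replicon: no skew transition called")
    cum = profile.cumulative
    span = float(cum.max() - cum.min())
    if span < flat_tolerance:
        return OriginCall(None, None, notes=f"no skew transition (range {span:.3g})")
    mids = profile.midpoints
    ori = int(mids[int(np.argmin(cum))])
    ter = int(mids[int(np.argmax(cum))])
    return OriginCall(oriC=ori, terminus=ter,
                      notes=f"cumulative-skew extrema over {len(cum)} windows")


def find_dnaa_boxes(
    record: SeqRecord,
    motif: str = "TTATCCACA",
    max_mismatch: int = 0,
    region: tuple[int, int] | None = None,
) -> list[tuple[int, str, int]]:
    """All motif occurrences on both strands within a Hamming distance.

    Returns ``(start, strand, mismatches)`` with start on the forward strand.
    N never matches.  ``region=(lo, hi)`` restricts starts to a (possibly
    origin-wrapping) coordinate interval.
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("empty motif")
    L = record.length
    m = len(motif)
    seq = record.sequence
    circular = record.topology == "circular"
    scan = seq + (seq[: m - 1] if circular else "")
    enc = _encode(scan)
    n_pos = len(scan) - m + 1
    hits = []
    for strand, pat in (("+", motif), ("-", revcomp(motif))):
        mism = np.zeros(n_pos, dtype=np.int32)
        for j, ch in enumerate(pat):
            mism += (enc[j : j + n_pos] != ord(ch)).astype(np.int32)
        # N anywhere in the window is a hard non-match
        n_mask = np.zeros(n_pos, dtype=bool)
        isn = enc == ord("N")
        for j in range(m):
            n_mask |= isn[j : j + n_pos]
        for pos in np.nonzero((mism <= max_mismatch) & ~n_mask)[0]:
            hits.append((int(pos) % L, strand, int(mism[pos])))
    if region is not None:
        lo, hi = region
        if lo <= hi:
            hits = [h for h in hits if lo <= h[0] < hi]
        else:  # wraps the origin
            hits = [h for h in hits if h[0] >= lo or h[0] < hi]
    return sorted(set(hits))


def distance_upstream(box_coord: int, gene: Feature, length: int) -> int:
    """Circular distance from a motif start to a gene's start codon, measured
    in the gene's upstream direction.

    For a + strand gene the start codon is ``gene.start`` and upstream lies at
    lower coordinates; for a - strand gene it is ``gene.end - 1`` and upstream
    lies at higher coordinates.  The result is in ``[0, length)``.
    """
    if gene.strand == 1:
        return (gene.start - box_coord) % length
    return (box_coord - (gene.end - 1)) % length


def profile_table(profile: SkewProfile):
    """Profile as a DataFrame (window_start, window_mid, value, cumulative)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "window_start": profile.starts,
            "window_mid": profile.midpoints,
            "value": profile.values,
            "cumulative": profile.cumulative,
        }
    )
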