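"""Design-vs-build verification: perfect-match diffing, repeat calling,
growth fitting.

The perfect-match landscape is a desk-scale analog of read-based
perfect-match genotyping: a design position counts as covered when at
least one k-mer window containing it occurs exactly (either strand) in
the assembled contigs. Uncovered runs expose substitutions/indels,
k-mer multiplicity ratios expose amplifications, and contig k-mers
absent from the design anchored between mapped flanks expose foreign
insertions (e.g. a vector backbone or transposase cassette riding in
with a synthesis chunk).

Repeat calling mirrors depth-based copy-number analysis: per-base depth
normalized to the genome-wide mean, thresholded, merged, and rounded to
an integer tandem copy number.

Growth rates are ordinary least squares of ln(OD) on time over an
exponential-phase window: mu (h^-1), intercept, and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .recoding import revcomp


class VerificationError(ValueError):
    pass


@dataclass
class DepthTrack:
    reference_id: str
    values: np.ndarray           # per-window depth, windows tile the reference
    window_size: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise VerificationError("negative depth")


@dataclass
class RepeatCall:
    start: int
    end: int
    mean_normalized_depth: float
    copy_number: int


@dataclass
class Deviation:
    type: str                    # uncovered | foreign_insertion | amplification
    start: int
    end: int
    evidence: dict = field(default_factory=dict)


@dataclass
class DesignDiff:
    deviations: list[Deviation]
    coverage_mask: np.ndarray    # per design base

    @property
    def covered_fraction(self) -> float:
        return float(self.coverage_mask.mean())

    def of_type(self, t: str) -> list[Deviation]:
        return [d for d in self.deviations if d.type == t]


@dataclass
class GrowthFit:
    mu: float                    # h^-1
    intercept: float             # ln(OD) at t=0
    r_squared: float
    window: tuple[float, float]
    n_points: int


# ---------------------------------------------------------------------------
# perfect-match landscape
# ---------------------------------------------------------------------------

def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        c = _canon(seq[i:i + k])
        out[c] = out.get(c, 0) + 1
    return out


def perfect_match_landscape(design: str, contigs: list[str], k: int = 50,
                            amplification_ratio: float = 1.75,
                            min_foreign_bp: int = 50) -> DesignDiff:
    """Perfect-match comparison of assembled contigs against the design.

    Returns a DesignDiff with uncovered runs, amplification calls (windows
    whose contig/design k-mer multiplicity ratio exceeds
    ``amplification_ratio``) and anchored foreign insertions with an
    estimated inserted length >= ``min_foreign_bp``.
    """
    design = design.upper()
    n = len(design)
    if k < 15:
        raise VerificationError("k must be >= 15")
    if k > n:
        raise VerificationError("k larger than design")
    if not contigs:
        raise VerificationError("no contigs supplied")
    contigs = [c.upper() for c in contigs]

    contig_counts: dict[str, int] = {}
    for c in contigs:
        for kmer, cnt in _kmer_counts(c, k).items():
            contig_counts[kmer] = contig_counts.get(kmer, 0) + cnt
    design_counts = _kmer_counts(design, k)
    design_pos: dict[str, int] = {}
    for i in range(n - k + 1):
        design_pos.setdefault(_canon(design[i:i + k]), i)

    # per-base coverage: union of covered k-windows
    delta = np.zeros(n + 1, dtype=int)
    n_windows = n - k + 1
    ratios = np.zeros(n_windows)
    for i in range(n_windows):
        kc = _canon(design[i:i + k])
        cnt = contig_counts.get(kc, 0)
        if cnt:
            delta[i] += 1
            delta[i + k] -= 1
        ratios[i] = cnt / design_counts[kc]
    mask = np.cumsum(delta[:-1]) > 0

    deviations: list[Deviation] = []
    for s, e in _runs(~mask):
        deviations.append(Deviation("uncovered", s, e,
                                    {"length": e - s}))
    amp_windows = ratios > amplification_ratio
    for s, e in _runs(amp_windows):
        deviations.append(Deviation(
            "amplification", s, e + k - 1,
            {"mean_ratio": float(ratios[s:e].mean()),
             "copy_number": int(round(float(ratios[s:e].mean())))}))

    deviations.extend(_foreign_insertions(
        contigs, contig_counts, design_counts, design_pos, k, min_foreign_bp))
    deviations.sort(key=lambda d: (d.start, d.end, d.type))
    return DesignDiff(deviations, mask)


def _runs(mask: np.ndarray):
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    yield from ((int(s), int(e)) for s, e in zip(starts, ends))


def _foreign_insertions(contigs, contig_counts, design_counts, design_pos,
                        k, min_foreign_bp):
    out = []
    for ci, contig in enumerate(contigs):
        m = len(contig) - k + 1
        if m <= 0:
            continue
        known = np.array([
            _canon(contig[i:i + k]) in design_counts for i in range(m)])
        for s, e in _runs(~known):
            if s == 0 or e == m:
                continue  # needs mapped flanks on both sides
            est_len = int((e - s) - (k - 1))
            if est_len < min_foreign_bp:
                continue
            left = _canon(contig[s - 1:s - 1 + k])
            right = _canon(contig[e:e + k])
            anchor_l = design_pos.get(left)
            anchor_r = design_pos.get(right)
            if anchor_l is None or anchor_r is None:
                continue
            pos = anchor_l + k
            out.append(Deviation(
                "foreign_insertion", pos, max(pos, anchor_r),
                {"contig": ci, "inserted_bp_estimate": est_len}))
    return out


def brute_force_coverage(design: str, contigs: list[str], k: int) -> np.ndarray:
    """Independent oracle: for every k-window of the design, substring-search
    both orientations in every contig; a position is covered iff a matching
    window contains it. Quadratic; test-scale only."""
    n = len(design)
    mask = np.zeros(n, dtype=bool)
    for i in range(n - k + 1):
        w = design[i:i + k]
        wrc = revcomp(w)
        if any(w in c or wrc in c for c in contigs):
            mask[i:i + k] = True
    return mask


# ---------------------------------------------------------------------------
# repeat calling from depth
# ---------------------------------------------------------------------------

def call_repeats(track: DepthTrack, min_region_bp: int = 1000,
                 threshold: float = 1.75, gap_bp: int = 200,
                 bin_bp: int = 100) -> list[RepeatCall]:
    """Call amplified regions from a depth track.

    Depth is averaged into ``bin_bp`` bins (taming Poisson noise) and
    normalized to the genome-wide mean, so the caller is invariant to
    global depth scaling. Maximal bin runs above ``threshold`` are merged
    across gaps <= ``gap_bp`` and filtered to >= ``min_region_bp``. The
    background mean is then re-estimated excluding the called regions --
    a large amplification inflates the naive genome-wide mean and would
    otherwise bias copy numbers low -- and each region is reported with
    copy number = round(mean depth / background mean).
    """
    mean = track.values.mean()
    if mean <= 0:
        raise VerificationError("zero mean depth")
    w = track.window_size
    vals = track.values
    nbins = len(vals) // max(1, bin_bp // w)
    per_bin = max(1, bin_bp // w)
    if nbins < 1:
        nbins, per_bin = len(vals), 1
    binned = vals[:nbins * per_bin].reshape(nbins, per_bin).mean(axis=1)
    norm = binned / mean
    above = norm > threshold
    merged: list[list[int]] = []
    for s, e in _runs(above):
        if merged and (s - merged[-1][1]) * per_bin * w <= gap_bp:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    merged = [(s, e) for s, e in merged
              if (e - s) * per_bin * w >= min_region_bp]
    if not merged:
        return []
    bg_mask = np.ones(nbins, dtype=bool)
    for s, e in merged:
        bg_mask[s:e] = False
    background = binned[bg_mask].mean() if bg_mask.any() else mean
    out = []
    for s, e in merged:
        m = float(binned[s:e].mean() / background)
        cn = int(round(m))
        if cn >= 2:
            out.append(RepeatCall(s * per_bin * w, e * per_bin * w, m, cn))
    return out


def read_bedgraph(path, reference_id: str | None = None,
                  length: int | None = None) -> DepthTrack:
    """Load a per-base depth track from a bedGraph file (0-based intervals)."""
    spans = []
    ref = reference_id
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, s, e, v = line.split("\t")
            if ref is None:
                ref = chrom
            if chrom != ref:
                continue
            spans.append((int(s), int(e), float(v)))
    if not spans:
        raise VerificationError(f"no depth intervals for {ref!r} in {path}")
    n = length or max(e for _, e, _ in spans)
    vals = np.zeros(n)
    for s, e, v in spans:
        vals[s:e] = v
    return DepthTrack(ref or "ref", vals, 1)


def write_bedgraph(track: DepthTrack, path) -> None:
    vals = track.values
    w = track.window_size
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start]:
                fh.write(f"{track.reference_id}\t{start * w}\t{i * w}\t"
                         f"{vals[start]:g}\n")
                start = i


# ---------------------------------------------------------------------------
# growth fitting
# ---------------------------------------------------------------------------

def estimate_growth_rate(times, ods, window: tuple[float, float] | None = None,
                         window_points: int = 5) -> GrowthFit:
    """Fit exponential growth: OLS of ln(OD) on t.

    ``window`` selects an explicit [t_start, t_end] interval; otherwise a
    sliding window of ``window_points`` consecutive samples is scanned and
    the maximum-R^2 window is fitted (the exponential phase). Constant OD
    yields mu = 0 with R^2 reported as 0 by convention.
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if t.shape != od.shape or t.ndim != 1:
        raise VerificationError("times and ods must be equal-length 1-D")
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        return _fit(t[sel], od[sel])
    if len(t) <= window_points:
        return _fit(t, od)
    best = None
    for i in range(len(t) - window_points + 1):
        fit = _fit(t[i:i + window_points], od[i:i + window_points])
        if best is None or fit.r_squared > best.r_squared:
            best = fit
    return best


def _fit(t: np.ndarray, od: np.ndarray) -> GrowthFit:
    if len(t) < 3:
        raise VerificationError("fit needs >= 3 points")
    if (od <= 0).any():
        raise VerificationError("non-positive OD in fit window")
    y = np.log(od)
    if np.allclose(y, y[0]):
        return GrowthFit(0.0, float(y[0]), 0.0,
                         (float(t[0]), float(t[-1])), len(t))
    res = stats.linregress(t, y)
    return GrowthFit(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2),
                     (float(t[0]), float(t[-1])), len(t))
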