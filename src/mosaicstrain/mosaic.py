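"""SNV-density windowing, divergent-cluster segmentation, identity
fractions, ancestry sharing and tiling-array overlap.

A mosaic laboratory strain is a patchwork of chromosome segments inherited
from different ancestors.  Against the reference ancestor most of the
genome is virtually identical (SNV density at or below ``t_ident``, default
0.5 SNV/kb) while introgressed blocks form distinct clusters of much higher
density (above ``t_div``, default 1 SNV/kb).  The module tiles each
chromosome into fixed windows (default 5 kb), classifies the windows,
merges maximal divergent runs into clusters (discarding runs shorter than
``min_cluster_len``, default 15 kb), and reports per-chromosome and
genome-wide identity fractions.

Clusters are further binned by their median window density: 2–5 SNV/kb
("moderate") and 9–12 SNV/kb ("high") — the two empirical divergence
classes seen between related laboratory strains — with everything else
"other".
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from mosaicstrain.variants import Callset, Variant, classify

__all__ = [
    "Window",
    "WindowTrack",
    "Cluster",
    "MosaicReport",
    "ArrayCall",
    "window_density",
    "segment_clusters",
    "fractions",
    "share_with_strain",
    "array_overlap",
]

DEFAULT_WINDOW = 5000
T_IDENT = 0.5
T_DIV = 1.0
MIN_CLUSTER_LEN = 15000
MODERATE_BIN = (2.0, 5.0)
HIGH_BIN = (9.0, 12.0)


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int
    snv_count: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        """SNVs per kb, normalized by the window's true length."""
        return self.snv_count / (self.length / 1000.0)

    def wclass(self, t_ident: float = T_IDENT, t_div: float = T_DIV) -> str:
        d = self.density
        if d <= t_ident:
            return "identical"
        if d > t_div:
            return "divergent"
        return "ambiguous"


@dataclass
class WindowTrack:
    windows: list[Window]
    chrom_lengths: dict[str, int]
    window_len: int = DEFAULT_WINDOW

    def per_chrom(self) -> dict[str, list[Window]]:
        out: dict[str, list[Window]] = {c: [] for c in self.chrom_lengths}
        for w in self.windows:
            out[w.chrom].append(w)
        return out

    @property
    def total_snvs(self) -> int:
        return sum(w.snv_count for w in self.windows)

    def to_wig(self) -> str:
        """Per-window density as fixed-step WIG (one track per chromosome)."""
        lines = []
        for chrom, wins in self.per_chrom().items():
            lines.append(
                f"fixedStep chrom={chrom} start=1 step={self.window_len} "
                f"span={self.window_len}"
            )
            lines.extend(f"{w.density:.4f}" for w in wins)
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class Cluster:
    chrom: str
    start: int  # 0-based half-open
    end: int
    median_density: float
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def divergence_class(self) -> str:
        if MODERATE_BIN[0] <= self.median_density <= MODERATE_BIN[1]:
            return "moderate"
        if HIGH_BIN[0] <= self.median_density <= HIGH_BIN[1]:
            return "high"
        return "other"


def window_density(
    callset: Callset | Iterable[Variant],
    chrom_lengths: Mapping[str, int],
    window_len: int = DEFAULT_WINDOW,
    snvs_only: bool = True,
) -> WindowTrack:
    """Tile each chromosome from position 0 and count SNVs per window.

    The final partial window keeps its true (shorter) length for density
    normalization; partial windows shorter than 1 kb are merged into the
    previous window.  Indels are excluded from density by default.
    """
    variants = list(callset)
    if snvs_only:
        variants = [v for v in variants if classify(v) == "SNP"]
    positions: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for v in variants:
        if v.chrom not in chrom_lengths:
            raise KeyError(f"variant on unknown chromosome {v.chrom}")
        if v.pos > chrom_lengths[v.chrom]:
            raise IndexError(
                f"variant at {v.chrom}:{v.pos} beyond chromosome end "
                f"({chrom_lengths[v.chrom]})"
            )
        positions[v.chrom].append(v.pos - 1)  # to 0-based
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        pos = sorted(positions[chrom])
        bounds = list(range(0, length, window_len)) + [length]
        # merge a trailing fragment < 1 kb into the previous window
        if len(bounds) >= 3 and bounds[-1] - bounds[-2] < 1000:
            del bounds[-2]
        for s, e in zip(bounds, bounds[1:]):
            lo = bisect.bisect_left(pos, s)
            hi = bisect.bisect_left(pos, e)
            windows.append(Window(chrom, s, e, hi - lo))
    return WindowTrack(windows, dict(chrom_lengths), window_len)


def segment_clusters(
    track: WindowTrack,
    t_ident: float = T_IDENT,
    t_div: float = T_DIV,
    min_cluster_len: int = MIN_CLUSTER_LEN,
) -> list[Cluster]:
    """Merge maximal runs of divergent windows into clusters.

    Ambiguous windows (density between the two thresholds) adjacent to a
    divergent run on either side are absorbed into it; isolated ambiguous
    windows count as identical.  Runs spanning less than
    ``min_cluster_len`` are discarded (their windows revert to identical
    for fraction purposes).  The cluster's density is the median of its
    member windows' densities.
    """
    clusters: list[Cluster] = []
    for chrom, wins in track.per_chrom().items():
        classes = [w.wclass(t_ident, t_div) for w in wins]
        # single-pass absorption: an ambiguous window directly adjacent to
        # a divergent window joins the run; longer ambiguous chains revert
        # to identical (keeps boundary error within one window)
        original = list(classes)
        for i, c in enumerate(original):
            if c != "ambiguous":
                continue
            left = original[i - 1] if i > 0 else None
            right = original[i + 1] if i + 1 < len(original) else None
            if left == "divergent" or right == "divergent":
                classes[i] = "divergent"
        i = 0
        while i < len(classes):
            if classes[i] != "divergent":
                i += 1
                continue
            j = i
            while j + 1 < len(classes) and classes[j + 1] == "divergent":
                j += 1
            start, end = wins[i].start, wins[j].end
            if end - start >= min_cluster_len:
                dens = median(w.density for w in wins[i : j + 1])
                clusters.append(Cluster(chrom, start, end, dens))
            i = j + 1
    return clusters


@dataclass
class MosaicReport:
    percent_identical_by_chrom: dict[str, float]
    percent_identical_genome: float
    median_percent_divergent: float
    total_divergent_bp: int
    clusters: list[Cluster]

    def to_tsv(self) -> str:
        lines = ["chrom\tpercent_identical\tpercent_divergent"]
        for chrom, pid in self.percent_identical_by_chrom.items():
            lines.append(f"{chrom}\t{pid:.1f}\t{100.0 - pid:.1f}")
        lines.append("")
        lines.append(f"genome_percent_identical\t{self.percent_identical_genome:.1f}")
        lines.append(
            f"median_percent_divergent_per_chrom\t{self.median_percent_divergent:.1f}"
        )
        lines.append(f"total_divergent_span_bp\t{self.total_divergent_bp}")
        return "\n".join(lines) + "\n"


def fractions(track: WindowTrack, clusters: Sequence[Cluster]) -> MosaicReport:
    """Identity fractions from the cluster complement.

    Per chromosome: percent identical = 100 x (length - sum of cluster
    lengths) / length.  The genome-wide figure uses total lengths; the
    median across chromosomes of (100 - percent identical) is also
    reported.
    """
    span: dict[str, int] = {c: 0 for c in track.chrom_lengths}
    for cl in clusters:
        span[cl.chrom] += cl.length
    per_chrom = {
        chrom: 100.0 * (length - span[chrom]) / length
        for chrom, length in track.chrom_lengths.items()
    }
    total_len = sum(track.chrom_lengths.values())
    total_span = sum(span.values())
    genome = 100.0 * (total_len - total_span) / total_len
    med_div = median(100.0 - p for p in per_chrom.values()) if per_chrom else 0.0
    return MosaicReport(
        percent_identical_by_chrom=per_chrom,
        percent_identical_genome=genome,
        median_percent_divergent=med_div,
        total_divergent_bp=total_span,
        clusters=list(clusters),
    )


@dataclass(frozen=True)
class SharingResult:
    cluster: Cluster
    shared: bool
    diff_density: float
    window_states: tuple[bool, ...]
    breakpoints: tuple[int, ...]  # genome positions of state flips


def share_with_strain(
    sample_callset: Callset,
    other_callset: Callset,
    clusters: Sequence[Cluster],
    window_len: int = DEFAULT_WINDOW,
    share_thresh: float = 0.5,
    t_div: float = T_DIV,
) -> list[SharingResult]:
    """Attribute divergent clusters to an ancestry shared with another
    strain sequenced against the same reference.

    Within each cluster the pairwise difference density between sample and
    other strain counts positions where their alleles differ (a position
    absent from a callset carries the reference allele).  A cluster is
    "shared" when that density is at most ``share_thresh`` SNV/kb while
    the sample still diverges from the reference above ``t_div`` — i.e.
    both strains carry the same non-reference haplotype.  Sharing is
    evaluated per window first; a breakpoint is reported at every window
    boundary inside a cluster where the sharing state flips.
    """
    sample = {(v.chrom, v.pos): v.alt for v in sample_callset.snvs()}
    other = {(v.chrom, v.pos): v.alt for v in other_callset.snvs()}
    results: list[SharingResult] = []
    for cl in clusters:
        bounds = list(range(cl.start, cl.end, window_len)) + [cl.end]
        if len(bounds) >= 3 and bounds[-1] - bounds[-2] < 1000:
            del bounds[-2]
        states: list[bool] = []
        breakpoints: list[int] = []
        total_diff = 0
        for s, e in zip(bounds, bounds[1:]):
            diff = 0
            samp = 0
            for pos in range(s + 1, e + 1):  # 1-based positions in window
                key = (cl.chrom, pos)
                a = sample.get(key)
                b = other.get(key)
                if a is not None:
                    samp += 1
                if a != b:
                    diff += 1
            total_diff += diff
            kb = (e - s) / 1000.0
            states.append(diff / kb <= share_thresh and samp / kb > t_div)
        for (s, e), prev, cur in zip(zip(bounds, bounds[1:]), states, states[1:]):
            if prev != cur:
                breakpoints.append(e)
        diff_density = total_diff / (cl.length / 1000.0)
        samp_density = sum(
            1 for (c, p) in sample if c == cl.chrom and cl.start < p <= cl.end
        ) / (cl.length / 1000.0)
        shared = diff_density <= share_thresh and samp_density > t_div
        results.append(
            SharingResult(
                cluster=Cluster(
                    cl.chrom,
                    cl.start,
                    cl.end,
                    cl.median_density,
                    label="shared" if shared else "private",
                ),
                shared=shared,
                diff_density=diff_density,
                window_states=tuple(states),
                breakpoints=tuple(breakpoints),
            )
        )
    return results


@dataclass(frozen=True)
class ArrayCall:
    chrom: str
    pos: int  # 1-based
    strain: str = ""


@dataclass(frozen=True)
class ArrayOverlap:
    matched: int
    total_snvs: int
    total_calls: int

    @property
    def percent(self) -> float:
        return 100.0 * self.matched / self.total_snvs if self.total_snvs else 0.0


def array_overlap(
    seq_callset: Callset,
    array_calls: Sequence[ArrayCall],
    tol_bp: int = 2,
    strain: str | None = None,
) -> ArrayOverlap:
    """Match tiling-array calls against sequencing SNVs with positional
    tolerance.

    Tiling arrays locate a SNV only to within a few bases, so an array
    call matches a sequencing SNV when it lies within ``tol_bp`` on the
    same chromosome.  Each array call matches at most one SNV — the
    nearest, leftmost on ties — and the overlap percent is matched SNVs
    over total sequencing SNVs.
    """
    calls = [c for c in array_calls if strain is None or c.strain == strain]
    snv_pos: dict[str, list[int]] = {}
    for v in seq_callset.snvs():
        snv_pos.setdefault(v.chrom, []).append(v.pos)
    for pos_list in snv_pos.values():
        pos_list.sort()
    matched: dict[str, set[int]] = {c: set() for c in snv_pos}
    total_snvs = sum(len(p) for p in snv_pos.values())
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos)):
        pos_list = snv_pos.get(call.chrom)
        if not pos_list:
            continue
        i = bisect.bisect_left(pos_list, call.pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pos_list):
                d = abs(pos_list[j] - call.pos)
                if d <= tol_bp and (
                    best is None
                    or d < best[0]
                    or (d == best[0] and pos_list[j] < best[1])
                ):
                    best = (d, pos_list[j])
        if best is not None:
            matched[call.chrom].add(best[1])
    n_matched = sum(len(s) for s in matched.values())
    return ArrayOverlap(
        matched=n_matched, total_snvs=total_snvs, total_calls=len(calls)
    )


def clusters_to_bed(clusters: Sequence[Cluster]) -> str:
    """BED (0-based half-open) with label, median density and class columns."""
    lines = []
    for cl in sorted(clusters, key=lambda c: (c.chrom, c.start)):
        lines.append(
            f"{cl.chrom}\t{cl.start}\t{cl.end}\t"
            f"{cl.label or cl.divergence_class}\t"
            f"{cl.median_density:.2f}\t{cl.divergence_class}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_array_tsv(path) -> list[ArrayCall]:
    """Read array calls from a TSV with columns chrom, pos[, strain]."""
    calls: list[ArrayCall] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            strain = parts[2] if len(parts) > 2 else ""
            calls.append(ArrayCall(parts[0], int(parts[1]), strain))
    return calls


def write_array_tsv(calls: Sequence[ArrayCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrain\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.strain}\n")
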