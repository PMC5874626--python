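"""T-RFLP fragment processing: electropherogram peaks to an OTU table.

A community fingerprint arrives as a flat peak table (sample, terminal
restriction fragment size in bp, fluorescence peak area).  The pipeline is:

1. :func:`filter_size_range` — keep fragments inside the sizing-standard
   window (default 50–550 bp, closed interval).
2. :func:`filter_noise` — per sample, iteratively split peaks into signal
   and baseline noise using a peak-area threshold of ``noise_factor`` times
   the zero-mean RMS of the not-yet-classified peaks.
3. :func:`bin_fragments` — align fragments across samples into OTUs with a
   single-linkage gap rule: sorted sizes chain into one bin while consecutive
   gaps stay within ``cluster_threshold`` bp.
4. :func:`standardize_relative` — per-sample relative abundance.
5. :func:`filter_otus` — drop singletons (OTUs seen in fewer than
   ``singleton_min_samples`` samples) and rare OTUs (mean relative abundance
   below ``min_total_abundance``); rows are deliberately not re-normalized.
6. :func:`log_transform` — ln(1 + 100·x) on relative fractions, zero-safe
   and monotone.

Peak tables are pandas DataFrames with columns ``sample_id``, ``size_bp``,
``area``; the OTU table is an :class:`OtuTable` wrapping a samples × OTUs
DataFrame plus per-OTU centroid and size-range metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError

PEAK_COLUMNS = ("sample_id", "size_bp", "area")


@dataclass(frozen=True)
class PeakRecord:
    """One electropherogram peak."""

    sample_id: str
    size_bp: float
    area: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise InputError(f"peak_area must be > 0, got {self.area}")
        if self.size_bp <= 0:
            raise InputError(f"fragment_size must be > 0, got {self.size_bp}")


@dataclass(frozen=True)
class TrflpConfig:
    """Tunable thresholds of the fragment pipeline (defaults are standard)."""

    size_min: float = 50.0
    size_max: float = 550.0
    noise_factor: float = 1.15
    cluster_threshold: float = 0.6
    min_total_abundance: float = 0.01
    singleton_min_samples: int = 2
    sigma_estimator: str = "rms"      # "rms" (zero-mean) or "sd"
    log_base: float = math.e
    abundance_rule: str = "mean"      # how "total abundance" is interpreted

    def __post_init__(self) -> None:
        if self.size_min >= self.size_max:
            raise InputError("size_min must be < size_max")
        if self.noise_factor < 0:
            raise InputError("noise_factor must be >= 0 (0 disables the filter)")
        if self.cluster_threshold <= 0:
            raise InputError("cluster_threshold must be > 0")
        if not (0.0 <= self.min_total_abundance < 1.0):
            raise InputError("min_total_abundance must be in [0,1)")
        if self.sigma_estimator not in ("rms", "sd"):
            raise InputError(f"unknown sigma_estimator {self.sigma_estimator!r}")


@dataclass
class OtuTable:
    """Sample × OTU abundance matrix with per-OTU fragment metadata.

    ``state`` records the abundance scale: "raw" (summed peak areas),
    "relative" (per-sample fractions) or "log" (transformed fractions).
    """

    data: pd.DataFrame                 # index: sample ids, columns: OTU ids
    centroids: pd.Series               # OTU id -> area-weighted mean size (bp)
    size_ranges: pd.DataFrame          # OTU id -> [size_min, size_max]
    state: str = "raw"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV with centroid/size-range metadata rows."""
        with open(path, "w") as fh:
            fh.write(f"# state\t{self.state}\n")
            fh.write("# centroid_bp\t" + "\t".join(
                f"{self.centroids[o]:.6g}" for o in self.otu_ids) + "\n")
            fh.write("# size_range_bp\t" + "\t".join(
                f"{self.size_ranges.loc[o, 'size_min']:.6g}-"
                f"{self.size_ranges.loc[o, 'size_max']:.6g}"
                for o in self.otu_ids) + "\n")
            self.data.to_csv(fh, sep="\t", index_label="sample_id",
                             float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        with open(path) as fh:
            state = fh.readline().strip().split("\t")[1]
            centroid_vals = [float(x) for x in fh.readline().strip().split("\t")[1:]]
            range_strs = fh.readline().strip().split("\t")[1:]
            data = pd.read_csv(fh, sep="\t", index_col="sample_id")
        otus = list(data.columns)
        centroids = pd.Series(centroid_vals, index=otus)
        ranges = pd.DataFrame(
            [[float(v) for v in s.split("-")] for s in range_strs],
            index=otus, columns=["size_min", "size_max"])
        return cls(data=data, centroids=centroids, size_ranges=ranges, state=state)


def _validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise InputError(f"peak table missing columns: {sorted(missing)}")
    if (peaks["area"] <= 0).any():
        raise InputError("peak areas must be > 0")
    if (peaks["size_bp"] <= 0).any():
        raise InputError("fragment sizes must be > 0")
    return peaks


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def filter_size_range(peaks: pd.DataFrame, config: TrflpConfig = TrflpConfig(),
                      ) -> pd.DataFrame:
    """Keep peaks with size_min <= size <= size_max (closed interval)."""
    _validate_peaks(peaks)
    mask = (peaks["size_bp"] >= config.size_min) & (peaks["size_bp"] <= config.size_max)
    return peaks.loc[mask].reset_index(drop=True)


def filter_noise_sample(areas: np.ndarray, config: TrflpConfig = TrflpConfig(),
                        ) -> tuple[np.ndarray, int]:
    """Iterative signal/noise partition of one sample's peak areas.

    Each pass computes sigma over the currently unclassified (noise) peaks —
    zero-mean RMS by default, sample SD optionally — and promotes to signal
    every peak with area > noise_factor × sigma, repeating until a fixed
    point.  Peaks move one way only, so the loop converges in at most n
    passes; the partition is independent of input order.

    Because the fixed point always leaves the smallest remaining peak below
    the threshold, at least one peak per sample ends as noise whenever
    noise_factor >= 1; ``noise_factor=0`` disables the filter entirely
    (every peak is signal), which is the appropriate setting for data known
    to carry no baseline noise.

    Returns a boolean signal mask and the number of passes taken.
    """
    areas = np.asarray(areas, float)
    signal = np.zeros(len(areas), dtype=bool)
    n_iter = 0
    while not signal.all():
        n_iter += 1
        noise = areas[~signal]
        if config.sigma_estimator == "rms":
            sigma = math.sqrt(float(np.mean(noise ** 2)))
        else:
            sigma = float(np.std(noise, ddof=1)) if len(noise) > 1 else 0.0
        promoted = (~signal) & (areas > config.noise_factor * sigma)
        if not promoted.any():
            break
        signal |= promoted
    return signal, n_iter


def filter_noise(peaks: pd.DataFrame, config: TrflpConfig = TrflpConfig(),
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a peak table into (signal, noise) per sample.

    A sample may end with zero signal peaks; such samples simply contribute
    nothing downstream (the removal is visible in the returned noise table).
    """
    _validate_peaks(peaks)
    if len(peaks) == 0:
        raise InputError("filter_noise requires at least one peak")
    signal_parts, noise_parts = [], []
    for _, sub in peaks.groupby("sample_id", sort=True):
        mask, _ = filter_noise_sample(sub["area"].to_numpy(), config)
        signal_parts.append(sub.loc[mask])
        noise_parts.append(sub.loc[~mask])
    signal = pd.concat(signal_parts).reset_index(drop=True)
    noise = pd.concat(noise_parts).reset_index(drop=True)
    return signal, noise


def bin_fragments(peaks: pd.DataFrame, config: TrflpConfig = TrflpConfig(),
                  ) -> OtuTable:
    """Align fragments across samples into OTUs by a single-linkage gap rule.

    All observed sizes are sorted; a new OTU starts whenever the gap to the
    previous observation exceeds ``cluster_threshold`` bp (chains can exceed
    the threshold in total width; the per-OTU size range records this).
    Within a bin, the centroid is the area-weighted mean size, and multiple
    peaks of one sample falling in one bin have their areas summed.
    """
    _validate_peaks(peaks)
    if len(peaks) == 0:
        raise InputError("bin_fragments requires at least one peak")
    ordered = peaks.sort_values("size_bp", kind="mergesort").reset_index(drop=True)
    sizes = ordered["size_bp"].to_numpy()
    new_bin = np.concatenate([[True], np.diff(sizes) > config.cluster_threshold])
    bin_idx = np.cumsum(new_bin) - 1
    ordered = ordered.assign(_bin=bin_idx)

    n_bins = bin_idx[-1] + 1
    width = max(3, len(str(n_bins)))
    otu_ids = [f"OTU{b + 1:0{width}d}" for b in range(n_bins)]

    centroids, ranges = {}, {}
    for b, grp in ordered.groupby("_bin"):
        oid = otu_ids[b]
        w = grp["area"].to_numpy()
        s = grp["size_bp"].to_numpy()
        centroids[oid] = float(np.sum(w * s) / np.sum(w))
        ranges[oid] = (float(s.min()), float(s.max()))

    samples = sorted(peaks["sample_id"].unique())
    mat = (ordered.assign(otu=[otu_ids[b] for b in ordered["_bin"]])
                  .pivot_table(index="sample_id", columns="otu", values="area",
                               aggfunc="sum", fill_value=0.0)
                  .reindex(index=samples, columns=otu_ids, fill_value=0.0))
    mat.columns.name = None
    mat.index.name = None
    range_df = pd.DataFrame.from_dict(ranges, orient="index",
                                      columns=["size_min", "size_max"]
                                      ).reindex(otu_ids)
    return OtuTable(data=mat.astype(float),
                    centroids=pd.Series(centroids).reindex(otu_ids),
                    size_ranges=range_df, state="raw")


def standardize_relative(table: OtuTable) -> OtuTable:
    """Divide each sample row by its total area; rows then sum to one."""
    if table.state != "raw":
        raise InputError(f"expected raw table, got state={table.state!r}")
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise InputError(f"zero-total sample(s): {list(zero.index)}")
    rel = table.data.div(totals, axis=0)
    return replace(table, data=rel, state="relative")


def filter_otus(table: OtuTable, config: TrflpConfig = TrflpConfig(),
                ) -> tuple[OtuTable, pd.DataFrame]:
    """Remove singleton and rare OTUs from a relative-abundance table.

    Singletons are OTUs nonzero in fewer than ``singleton_min_samples``
    samples.  Rare OTUs have "total abundance" below ``min_total_abundance``,
    where total abundance is by default the mean per-sample relative
    abundance (``abundance_rule="mean"``); ``"grand_total"`` interprets it as
    the OTU's share of the table-wide total instead.  Rows are NOT
    re-normalized after filtering, so the removed mass stays visible.

    Returns the filtered table and a removal report (otu_id, reason, metric).
    """
    if table.state != "relative":
        raise InputError(f"expected relative table, got state={table.state!r}")
    prevalence = (table.data > 0).sum(axis=0)
    if config.abundance_rule == "mean":
        abundance = table.data.mean(axis=0)
    elif config.abundance_rule == "grand_total":
        abundance = table.data.sum(axis=0) / table.data.to_numpy().sum()
    else:
        raise InputError(f"unknown abundance_rule {config.abundance_rule!r}")

    records = []
    keep = []
    for otu in table.otu_ids:
        if prevalence[otu] < config.singleton_min_samples:
            records.append((otu, "singleton", int(prevalence[otu])))
        elif abundance[otu] < config.min_total_abundance:
            records.append((otu, "low_abundance", float(abundance[otu])))
        else:
            keep.append(otu)
    if not keep:
        raise InputError("all OTUs removed by filtering (degenerate table)")
    report = pd.DataFrame(records, columns=["otu_id", "reason", "metric"])
    filtered = replace(table, data=table.data[keep],
                       centroids=table.centroids[keep],
                       size_ranges=table.size_ranges.loc[keep])
    return filtered, report


def log_transform(table: OtuTable, config: TrflpConfig = TrflpConfig(),
                  ) -> OtuTable:
    """Entrywise log(1 + 100·x) of relative fractions (natural log default).

    The percentage-scale log(1+p) keeps zeros at zero and preserves ordering.
    """
    if table.state != "relative":
        raise InputError(f"expected relative table, got state={table.state!r}")
    if (table.data.to_numpy() < 0).any():
        raise InputError("negative abundance in relative table")
    transformed = np.log1p(100.0 * table.data) / math.log(config.log_base)
    return replace(table, data=transformed, state="log")


def run_pipeline(peaks: pd.DataFrame, config: TrflpConfig = TrflpConfig(),
                 ) -> dict[str, object]:
    """Full fragment pipeline; returns every intermediate product.

    Keys: ``sized`` (peaks in window), ``signal``/``noise`` (peak split),
    ``raw``, ``relative``, ``filtered``, ``removal_report``, ``log``.
    """
    sized = filter_size_range(peaks, config)
    signal, noise = filter_noise(sized, config)
    raw = bin_fragments(signal, config)
    relative = standardize_relative(raw)
    filtered, report = filter_otus(relative, config)
    logged = log_transform(filtered, config)
    return {"sized": sized, "signal": signal, "noise": noise, "raw": raw,
            "relative": relative, "filtered": filtered,
            "removal_report": report, "log": logged}
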