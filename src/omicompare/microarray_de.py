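"""Z-ratio differential expression for small-replicate two-group microarrays.

The statistic chain is the classic spreadsheet-era one for Illumina/cDNA
arrays with very few biological replicates per group:

1. *Global normalization* — every array (column) is rescaled so that its
   total intensity equals the mean total over all arrays.
2. *Log10 Z-scoring* — each array's log10 intensities are standardized to
   mean 0 / SD 1, removing array-level location and scale effects.
3. *Z-ratio* — the per-gene difference of group-mean Z-scores, divided by
   the standard deviation of those differences across **all** genes.  The
   Z-ratio is a standardized fold-change surrogate: it expresses each
   gene's change in units of the typical change seen on the platform, so
   the returned vector always has (sample) standard deviation 1.
4. *Z-test* — a per-gene two-sample test on the replicate Z-scores,
   referred to the standard normal; it measures reproducibility of the
   change across biological replicates.
5. *BH-FDR* — Benjamini–Hochberg step-up adjustment of the Z-test p-values.

A gene is called up/down when (|Z-ratio| >= 1.5 OR p < 0.05) AND q < 0.05
under the default gates; each gate can be switched off independently.

:class:`ZRatioModel` / :class:`ZRatioResults` wrap the chain in a
model-object API; the stage functions are public for piecemeal use.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntensityMatrix",
    "ZScoreMatrix",
    "ZRatioModel",
    "ZRatioResults",
    "global_normalize",
    "log_zscore",
    "z_ratio",
    "z_test",
    "bh_fdr",
    "call_significance",
]


@dataclass
class IntensityMatrix:
    """Gene x sample raw intensities plus per-sample metadata.

    ``values`` is a genes-as-rows DataFrame whose columns are unique sample
    ids; ``sample_meta`` is indexed by sample id with at least a
    ``genotype`` column (``control`` / ``case``) and optional ``tissue`` and
    ``replicate`` columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        if not set(self.values.columns) <= set(self.sample_meta.index):
            raise ValueError("sample_meta missing entries for some samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, genotype: str) -> list[str]:
        """Sample ids whose metadata genotype equals ``genotype``."""
        meta = self.sample_meta.loc[self.values.columns]
        return list(meta.index[meta["genotype"] == genotype])

    @classmethod
    def concat(cls, matrices: Sequence["IntensityMatrix"]) -> "IntensityMatrix":
        values = pd.concat([m.values for m in matrices], axis=1)
        meta = pd.concat([m.sample_meta for m in matrices], axis=0)
        return cls(values=values, sample_meta=meta)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, sample_meta: pd.DataFrame = None) -> "IntensityMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, sample_meta=sample_meta)


@dataclass
class ZScoreMatrix:
    """Per-array standardized log-intensities with provenance."""

    z: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.z.to_numpy(float)
        if not (np.abs(arr.mean(axis=0)) < 1e-9).all():
            raise ValueError("z-score columns must have mean 0")
        if not (np.abs(arr.std(axis=0, ddof=1) - 1.0) < 1e-9).all():
            raise ValueError("z-score columns must have SD 1")


def global_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Rescale each array so its total intensity equals the across-array mean.

    The per-array correction factor is ``mean(all array totals) / array
    total``; within-array relative structure is untouched.  Raises if any
    array has zero total intensity.
    """
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with non-positive total intensity: {list(zero.index)}")
    factors = totals.mean() / totals
    return IntensityMatrix(values=m.values * factors, sample_meta=m.sample_meta)


def log_zscore(m: IntensityMatrix, floor: float = 1.0) -> ZScoreMatrix:
    """Standardize log10 intensities within each array.

    Intensities below ``floor`` are clipped up to it before the log, which
    both guards the transform and acts as the low-signal filter.  Columns
    are standardized with the sample SD (``ddof=1``, the spreadsheet STDEV
    convention of the method's lineage, e.g. log10 {10,100,1000} maps to
    z = {-1, 0, +1}).  A constant column (zero variance) is an error.
    """
    vals = m.values.clip(lower=floor)
    logged = np.log10(vals)
    sd = logged.std(axis=0, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"constant (zero-variance) sample(s): {list(flat.index)}")
    z = (logged - logged.mean(axis=0)) / sd
    return ZScoreMatrix(z=z, provenance={"log_base": 10, "sd_ddof": 1, "floor": floor})


def _check_groups(z: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]) -> None:
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if a & b:
        raise ValueError(f"groups overlap: {sorted(a & b)}")
    missing = (a | b) - set(z.columns)
    if missing:
        raise KeyError(f"unknown sample ids: {sorted(missing)}")


def z_ratio(zs: ZScoreMatrix, group_a: Sequence[str], group_b: Sequence[str]) -> pd.Series:
    """Per-gene Z-ratio between two disjoint sample groups.

    ``d = mean_z(group_a) - mean_z(group_b)`` per gene; the Z-ratio is
    ``d / sd(d)`` with the sample (ddof=1) SD taken across genes, so the
    result has unit SD.  An all-zero ``d`` vector returns zeros rather than
    dividing by zero.
    """
    _check_groups(zs.z, group_a, group_b)
    d = zs.z[list(group_a)].mean(axis=1) - zs.z[list(group_b)].mean(axis=1)
    sd = d.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return pd.Series(np.zeros(len(d)), index=d.index, name="z_ratio")
    return (d / sd).rename("z_ratio")


def z_test(zs: ZScoreMatrix, group_a: Sequence[str], group_b: Sequence[str]) -> pd.Series:
    """Two-sided per-gene Z-test on replicate Z-scores.

    statistic = (mean_a - mean_b) / sqrt(var_a/n_a + var_b/n_b), referred
    to the standard normal.  Requires >= 2 samples per group (the variance
    is estimated with ddof=1).  A gene with zero pooled SE gets p = 1 when
    the means agree and p = 0 otherwise.
    """
    _check_groups(zs.z, group_a, group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples for the Z-test")
    za = zs.z[list(group_a)]
    zb = zs.z[list(group_b)]
    diff = za.mean(axis=1) - zb.mean(axis=1)
    se = np.sqrt(za.var(axis=1, ddof=1) / len(group_a) + zb.var(axis=1, ddof=1) / len(group_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.Series(p, index=zs.z.index, name="p_value")


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significance(
    records: pd.DataFrame,
    zr_threshold: float = 1.5,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    use_z_ratio: bool = True,
    use_p: bool = True,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Assign up/down/ns calls to draft differential records.

    Default rule: (|z_ratio| >= 1.5 OR p < 0.05) AND q < 0.05.  The
    Z-ratio and p gates are OR-combined (either suffices); the FDR gate is
    AND-combined (must also hold).  Each gate is independently switchable;
    with both OR-gates off only the FDR gate applies.
    """
    out = records.copy()
    zr = out["z_ratio"].to_numpy(float)
    p = out["p_value"].to_numpy(float)
    q = out["q_value"].to_numpy(float)
    gates = []
    if use_z_ratio:
        gates.append(np.abs(zr) >= zr_threshold)
    if use_p:
        gates.append(p < p_threshold)
    passes = np.logical_or.reduce(gates) if gates else np.ones(len(out), dtype=bool)
    if use_fdr:
        passes = passes & (q < fdr_threshold)
    call = np.where(passes & (zr > 0), "up", np.where(passes & (zr < 0), "down", "ns"))
    out["call"] = call
    return out


class ZRatioModel:
    """Two-group Z-ratio differential-expression model.

    Parameters
    ----------
    matrix
        Raw intensities with sample metadata, or a bare DataFrame when
        ``case``/``control`` list sample ids explicitly.
    case, control
        Sample-id lists; defaults read genotype ``case``/``control`` from
        the matrix metadata.  The Z-ratio is case minus control.
    floor
        Intensity floor applied before the log10 transform.
    """

    def __init__(
        self,
        matrix: IntensityMatrix | pd.DataFrame,
        case: Sequence[str] | None = None,
        control: Sequence[str] | None = None,
        floor: float = 1.0,
    ):
        if isinstance(matrix, pd.DataFrame):
            matrix = IntensityMatrix(values=matrix)
        self.matrix = matrix
        self.case = list(case) if case is not None else matrix.samples_for("case")
        self.control = list(control) if control is not None else matrix.samples_for("control")
        if not self.case or not self.control:
            raise ValueError("could not determine case/control sample groups")
        self.floor = floor

    def fit(
        self,
        zr_threshold: float = 1.5,
        p_threshold: float = 0.05,
        fdr_threshold: float = 0.05,
        use_z_ratio: bool = True,
        use_p: bool = True,
        use_fdr: bool = True,
    ) -> "ZRatioResults":
        normalized = global_normalize(self.matrix)
        zs = log_zscore(normalized, floor=self.floor)
        zr = z_ratio(zs, self.case, self.control)
        p = z_test(zs, self.case, self.control)
        records = pd.DataFrame({"z_ratio": zr, "p_value": p})
        records["q_value"] = bh_fdr(records["p_value"].to_numpy())
        records = call_significance(
            records,
            zr_threshold=zr_threshold,
            p_threshold=p_threshold,
            fdr_threshold=fdr_threshold,
            use_z_ratio=use_z_ratio,
            use_p=use_p,
            use_fdr=use_fdr,
        )
        thresholds = {
            "zr_threshold": zr_threshold,
            "p_threshold": p_threshold,
            "fdr_threshold": fdr_threshold,
            "use_z_ratio": use_z_ratio,
            "use_p": use_p,
            "use_fdr": use_fdr,
        }
        return ZRatioResults(self, zs, records, thresholds)


class ZRatioResults:
    """Fitted Z-ratio DE results: per-gene statistics, calls and summaries."""

    def __init__(self, model: ZRatioModel, zscores: ZScoreMatrix, records: pd.DataFrame, thresholds: dict):
        self.model = model
        self.zscores = zscores
        self.records = records
        self.thresholds = thresholds

    @property
    def up(self) -> pd.Index:
        return self.records.index[self.records["call"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.records.index[self.records["call"] == "down"]

    def summary(self) -> str:
        r = self.records
        buf = io.StringIO()
        buf.write("Z-ratio differential expression\n")
        buf.write("=" * 43 + "\n")
        buf.write(f"genes: {len(r)}   case n={len(self.model.case)}   control n={len(self.model.control)}\n")
        t = self.thresholds
        buf.write(
            f"gates: |Z-ratio| >= {t['zr_threshold']} (on={t['use_z_ratio']}) OR "
            f"p < {t['p_threshold']} (on={t['use_p']}); AND q < {t['fdr_threshold']} (on={t['use_fdr']})\n"
        )
        buf.write(f"calls: up={len(self.up)}  down={len(self.down)}  ns={(r['call'] == 'ns').sum()}\n")
        top = r.reindex(r["z_ratio"].abs().sort_values(ascending=False).index).head(10)
        buf.write("top |Z-ratio| genes:\n")
        buf.write(top.to_string(float_format=lambda v: f"{v:.4g}"))
        return buf.getvalue()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index_label="gene_id")

    def signed_set(self, label: str):
        """Export the significant calls as a signed gene set."""
        from .set_algebra import build_signed_set

        return build_signed_set(self.records, label)
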