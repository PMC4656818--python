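"""Protein quantification from 4-plex iTRAQ reporter-ion intensities.

The design quantified here pools the control genotype into reporter
channels 114 and 115 and the case genotype into 116 and 117.  Per peptide:

* ``r_ctrl = i114 / i115`` — the control-label ratio; a technical QC
  quantity that should sit near 1 for accurate labeling,
* ``r116 = i116 / mean(i114, i115)`` and ``r117 = i117 / mean(i114, i115)``
  — the case-vs-control expression ratios.

Peptide ratios are rolled up to the protein level by the median; proteins
whose control ratio falls outside the open interval (0.8, 1.2) fail QC and
are excluded from differential calling (but kept in the QC report).  A
QC-passing protein is called up/down when a case channel exceeds 1.2 or
drops below 0.8 (``channel_mode='any'``; ``'both'`` demands concordance of
both case channels); channels disagreeing in direction yield an
``unchanged`` call with a conflict flag.
"""

from __future__ import annotations

import io
import logging
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ReporterQuant",
    "ReporterQuantResults",
    "peptide_ratios",
    "aggregate_protein_ratios",
    "control_qc_filter",
    "differential_call",
    "read_peptide_table",
]

logger = logging.getLogger(__name__)

REPORTER_COLUMNS = ["peptide_id", "protein_id", "i114", "i115", "i116", "i117"]


def read_peptide_table(path) -> pd.DataFrame:
    """Read a peptide reporter-ion CSV with the canonical column set."""
    table = pd.read_csv(path)
    missing = [c for c in REPORTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing column(s): {missing}")
    return table


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REPORTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing column(s): {missing}")
    if len(table) == 0:
        raise ValueError("peptide table is empty")
    if (table[["i114", "i115", "i116", "i117"]].to_numpy(float) < 0).any():
        raise ValueError("reporter intensities must be nonnegative")
    multi = table.groupby("peptide_id")["protein_id"].nunique()
    if (multi > 1).any():
        raise ValueError(f"peptide(s) mapped to several proteins: {list(multi.index[multi > 1])}")
    return table


def peptide_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide control and case/control ratios; zero-denominator rows dropped."""
    table = _validate(table)
    ctrl_mean = (table["i114"] + table["i115"]) / 2.0
    usable = (table["i115"] > 0) & (ctrl_mean > 0)
    dropped = (~usable).sum()
    if dropped:
        logger.warning("skipping %d peptide(s) with zero denominator", dropped)
    t = table.loc[usable]
    return pd.DataFrame(
        {
            "protein_id": t["protein_id"],
            "r_ctrl": t["i114"] / t["i115"],
            "r116": t["i116"] / ctrl_mean.loc[usable],
            "r117": t["i117"] / ctrl_mean.loc[usable],
        },
        index=t.index,
    )


def aggregate_protein_ratios(table: pd.DataFrame, min_peptides: int = 1) -> pd.DataFrame:
    """Median peptide-ratio roll-up per protein.

    Proteins supported by fewer than ``min_peptides`` usable peptides are
    excluded with a warning (never an error).
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    ratios = peptide_ratios(table)
    grouped = ratios.groupby("protein_id")
    records = grouped[["r_ctrl", "r116", "r117"]].median()
    records["n_peptides"] = grouped.size()
    short = records.index[records["n_peptides"] < min_peptides]
    if len(short):
        logger.warning("excluding %d protein(s) with < %d usable peptides", len(short), min_peptides)
        records = records.drop(index=short)
    dropped = set(table["protein_id"]) - set(records.index)
    for pid in sorted(dropped - set(short)):
        logger.warning("protein %s has no usable peptides; excluded", pid)
    return records


def control_qc_filter(records: pd.DataFrame, lo: float = 0.8, hi: float = 1.2) -> pd.DataFrame:
    """Flag proteins whose 114:115 control ratio lies strictly inside (lo, hi).

    The bounds are strict: a control ratio of exactly 0.8 or 1.2 fails.
    Failing proteins stay in the table (for the QC report) but are barred
    from differential calls.
    """
    out = records.copy()
    r = out["r_ctrl"].to_numpy(float)
    out["qc_pass"] = (r > lo) & (r < hi)
    return out


def differential_call(
    records: pd.DataFrame,
    lo: float = 0.8,
    hi: float = 1.2,
    channel_mode: Literal["any", "both"] = "any",
) -> pd.DataFrame:
    """Call QC-passing proteins up/down from their case-channel ratios.

    ``any``: one case channel outside the limits suffices; if the two
    channels breach in opposite directions the protein is left
    ``unchanged`` with ``conflict=True``.  ``both``: both channels must be
    concordantly outside the limits.
    """
    if channel_mode not in ("any", "both"):
        raise ValueError(f"unknown channel_mode: {channel_mode!r}")
    out = records.copy()
    if "qc_pass" not in out.columns:
        raise ValueError("run control_qc_filter before differential_call")
    r116 = out["r116"].to_numpy(float)
    r117 = out["r117"].to_numpy(float)
    hi116, hi117 = r116 > hi, r117 > hi
    lo116, lo117 = r116 < lo, r117 < lo
    if channel_mode == "any":
        up = hi116 | hi117
        down = lo116 | lo117
        conflict = up & down
        up, down = up & ~conflict, down & ~conflict
    else:
        up = hi116 & hi117
        down = lo116 & lo117
        conflict = (hi116 & lo117) | (lo116 & hi117)
    qc = out["qc_pass"].to_numpy(bool)
    out["conflict"] = conflict & qc
    out["call"] = np.where(qc & up, "up", np.where(qc & down, "down", "unchanged"))
    return out


class ReporterQuant:
    """iTRAQ reporter-ion quantification model over a peptide table.

    Parameters
    ----------
    table
        Peptide rows with columns ``peptide_id, protein_id, i114, i115,
        i116, i117``.
    min_peptides
        Minimum usable peptides per reported protein (default 1 — a single
        compliant spectrum may quantify a protein).
    """

    def __init__(self, table: pd.DataFrame, min_peptides: int = 1):
        self.table = _validate(table)
        self.min_peptides = min_peptides

    def fit(
        self,
        lo: float = 0.8,
        hi: float = 1.2,
        channel_mode: Literal["any", "both"] = "any",
    ) -> "ReporterQuantResults":
        records = aggregate_protein_ratios(self.table, min_peptides=self.min_peptides)
        records = control_qc_filter(records, lo=lo, hi=hi)
        records = differential_call(records, lo=lo, hi=hi, channel_mode=channel_mode)
        return ReporterQuantResults(self, records, {"lo": lo, "hi": hi, "channel_mode": channel_mode})


class ReporterQuantResults:
    """Protein-level ratios, QC flags and differential calls."""

    def __init__(self, model: ReporterQuant, records: pd.DataFrame, params: dict):
        self.model = model
        self.records = records
        self.params = params

    @property
    def up(self) -> pd.Index:
        return self.records.index[self.records["call"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.records.index[self.records["call"] == "down"]

    def qc_report(self) -> dict:
        r = self.records
        return {
            "n_proteins": int(len(r)),
            "n_qc_pass": int(r["qc_pass"].sum()),
            "n_qc_fail": int((~r["qc_pass"]).sum()),
            "n_conflict": int(r["conflict"].sum()),
            "control_ratio_limits": [self.params["lo"], self.params["hi"]],
            "channel_mode": self.params["channel_mode"],
        }

    def summary(self) -> str:
        r = self.records
        buf = io.StringIO()
        buf.write("iTRAQ reporter-ion quantification\n")
        buf.write("=" * 43 + "\n")
        buf.write(
            f"proteins: {len(r)}  QC pass: {int(r['qc_pass'].sum())} "
            f"(control 114:115 in ({self.params['lo']}, {self.params['hi']}))\n"
        )
        buf.write(
            f"calls ({self.params['channel_mode']} channel): up={len(self.up)}  "
            f"down={len(self.down)}  unchanged={(r['call'] == 'unchanged').sum()}"
            f"  conflicts={int(r['conflict'].sum())}\n"
        )
        extremes = r.loc[r["qc_pass"]]
        if len(extremes):
            top = extremes.reindex(
                (extremes[["r116", "r117"]].mean(axis=1) - 1).abs().sort_values(ascending=False).index
            ).head(10)
            buf.write("largest case/control departures:\n")
            buf.write(top.to_string(float_format=lambda v: f"{v:.4g}"))
        return buf.getvalue()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index_label="protein_id")

    def signed_set(self, label: str):
        from .set_algebra import SignedGeneSet

        members = {pid: +1 for pid in self.up}
        members.update({pid: -1 for pid in self.down})
        return SignedGeneSet(label=label, members=members)
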