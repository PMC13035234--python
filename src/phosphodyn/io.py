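"""Table I/O: phosphosite intensity tables, designs, and site assignments.

The canonical on-disk phospho table is long-format TSV with columns
``sample, time_min, site_id, value, replicate``; wide tables (sites x
sample@time columns) are accepted on read.  All times are minutes (floats);
all step indices elsewhere in the package are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rnn import PerturbationDesign
from .site_map import SiteAssignment

LONG_COLUMNS = ["sample", "time_min", "site_id", "value", "replicate"]


@dataclass
class PhosphoTimeCourse:
    """samples x timepoints x sites intensity tensor with a validity mask."""

    values: np.ndarray
    mask: np.ndarray
    sample_ids: list[str]
    times: np.ndarray
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.times = np.asarray(self.times, dtype=float)
        expected = (len(self.sample_ids), self.times.size, len(self.site_ids))
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(f"tensor shape {self.values.shape} != {expected}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample: str) -> int:
        return self.sample_ids.index(sample)

    def subset_samples(self, sample_ids: list[str]) -> "PhosphoTimeCourse":
        rows = [self.sample_ids.index(s) for s in sample_ids]
        return PhosphoTimeCourse(self.values[rows], self.mask[rows],
                                 list(sample_ids), self.times.copy(),
                                 list(self.site_ids))

    def subset_times(self, times: np.ndarray) -> "PhosphoTimeCourse":
        cols = [int(np.flatnonzero(np.isclose(self.times, t))[0]) for t in times]
        return PhosphoTimeCourse(self.values[:, cols], self.mask[:, cols],
                                 list(self.sample_ids),
                                 np.asarray(times, dtype=float),
                                 list(self.site_ids))

    def subset_sites(self, site_ids: list[str]) -> "PhosphoTimeCourse":
        cols = [self.site_ids.index(s) for s in site_ids]
        return PhosphoTimeCourse(self.values[:, :, cols], self.mask[:, :, cols],
                                 list(self.sample_ids), self.times.copy(),
                                 list(site_ids))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sample_ids):
            for k, t in enumerate(self.times):
                for j, site in enumerate(self.site_ids):
                    if self.mask[i, k, j]:
                        rows.append((s, float(t), site,
                                     float(self.values[i, k, j]), 1))
        return pd.DataFrame(rows, columns=LONG_COLUMNS)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "PhosphoTimeCourse":
        missing = [c for c in ("sample", "time_min", "site_id", "value")
                   if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns in phospho table: {missing}")
        sample_ids = sorted({str(s) for s in df["sample"]})
        times = np.array(sorted(df["time_min"].astype(float).unique()))
        site_ids = sorted({str(s) for s in df["site_id"]})
        shape = (len(sample_ids), times.size, len(site_ids))
        acc = np.zeros(shape)
        cnt = np.zeros(shape)
        si = {s: i for i, s in enumerate(sample_ids)}
        ti = {t: i for i, t in enumerate(times)}
        pi = {s: i for i, s in enumerate(site_ids)}
        for row in df.itertuples(index=False):
            i = si[str(row.sample)]
            k = ti[float(row.time_min)]
            j = pi[str(row.site_id)]
            acc[i, k, j] += float(row.value)
            cnt[i, k, j] += 1
        mask = cnt > 0
        values = np.divide(acc, cnt, out=np.zeros(shape), where=mask)
        return cls(values, mask, sample_ids, times, site_ids)


def read_phospho_table(path) -> PhosphoTimeCourse:
    """Read a long- or wide-format phospho table.

    Wide tables must carry a ``site_id`` column and ``SAMPLE@TIME`` value
    columns; they are pivoted to the canonical long layout on read.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if {"sample", "time_min", "site_id", "value"} <= set(df.columns):
        return PhosphoTimeCourse.from_long_frame(df)
    if "site_id" in df.columns:
        value_cols = [c for c in df.columns if c != "site_id" and "@" in c]
        if value_cols:
            long = df.melt(id_vars="site_id", value_vars=value_cols,
                           var_name="key", value_name="value").dropna()
            long[["sample", "time_min"]] = long["key"].str.split("@", expand=True)
            long["time_min"] = long["time_min"].astype(float)
            long["replicate"] = 1
            return PhosphoTimeCourse.from_long_frame(long[LONG_COLUMNS])
    raise ValueError("unrecognized phospho-table layout")


def write_phospho_table(tc: PhosphoTimeCourse, path) -> None:
    # %.17g keeps the write -> read round trip bit-exact
    tc.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_site_assignment(path) -> SiteAssignment:
    return SiteAssignment.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_site_assignment(sa: SiteAssignment, path) -> None:
    sa.to_frame().to_csv(path, sep="\t", index=False)


def read_design(design_path, drug_target_path, ligand_receptor_path) -> PerturbationDesign:
    design = pd.read_csv(design_path, sep="\t", dtype=str).fillna("")
    dt = pd.read_csv(drug_target_path, sep="\t", dtype=str)
    lr = pd.read_csv(ligand_receptor_path, sep="\t", dtype=str)
    return PerturbationDesign.from_frames(design, dt, lr)


def write_design(design: PerturbationDesign, design_path, drug_target_path,
                 ligand_receptor_path) -> None:
    d, dt, lr = design.to_frames()
    d.to_csv(design_path, sep="\t", index=False)
    dt.to_csv(drug_target_path, sep="\t", index=False)
    lr.to_csv(ligand_receptor_path, sep="\t", index=False)
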