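"""Aligned LC-MS feature tables: I/O, targeted matching, blank checks.

A feature table is the aligned export of a peak-picking pipeline: one row
per feature (m/z, retention time), one column per sample, cell = peak
height (empty = not detected / censored below the detection limit).
Sample names follow the grammar ``<compartment>_t<min>_r<rep>``, e.g.
``acceptor_t100_r2``.  Targeted matching mirrors a targeted peak
deconvolution step: each compound in a target list is looked up by m/z
(ppm tolerance) and retention time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .design import CompoundSpec

_SAMPLE_RE = re.compile(
    r"^(stock|donor|acceptor|membrane|blank_membrane|blank_buffer|calibration)"
    r"_t(\d+(?:\.\d+)?)_r(\d+)$"
)


def sample_name(compartment: str, time: float, replicate: int) -> str:
    t = f"{time:g}"
    return f"{compartment}_t{t}_r{replicate}"


def parse_sample_name(name: str) -> tuple[str, float, int]:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(f"sample name {name!r} does not follow <compartment>_t<min>_r<rep>")
    return m.group(1), float(m.group(2)), int(m.group(3))


@dataclass
class FeatureTable:
    """Feature (m/z, RT) metadata plus a feature x sample height matrix.

    ``intensities`` is indexed by feature_id with one column per sample;
    NaN marks an absent (censored) height.
    """

    features: pd.DataFrame  # columns: feature_id, mz, rt
    intensities: pd.DataFrame  # index: feature_id, columns: sample ids

    def __post_init__(self) -> None:
        f = self.features
        if f["feature_id"].duplicated().any():
            dupes = f.loc[f["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValueError(f"duplicate feature id(s): {dupes}")
        if pd.Index(self.intensities.columns).duplicated().any():
            raise ValueError("duplicate sample columns")
        if not np.all(np.isfinite(f["mz"])) or (f["mz"] <= 0).any():
            raise ValueError("mz values must be finite and positive")
        if not np.all(np.isfinite(f["rt"])) or (f["rt"] < 0).any():
            raise ValueError("rt values must be finite and non-negative")
        for name in self.intensities.columns:
            parse_sample_name(name)

    @classmethod
    def from_arrays(
        cls,
        features: list[tuple[str, float, float]],
        sample_ids: list[str],
        heights: np.ndarray,
    ) -> "FeatureTable":
        feats = pd.DataFrame(features, columns=["feature_id", "mz", "rt"])
        inten = pd.DataFrame(
            np.asarray(heights, dtype=float),
            index=feats["feature_id"],
            columns=sample_ids,
        )
        return cls(features=feats, intensities=inten)

    @property
    def samples(self) -> pd.DataFrame:
        """Sample metadata parsed from the column names."""
        rows = [(s, *parse_sample_name(s)) for s in self.intensities.columns]
        return pd.DataFrame(rows, columns=["sample_id", "compartment", "time", "replicate"])

    def sample_ids(
        self,
        compartment: str,
        time: float | None = None,
        replicate: int | None = None,
    ) -> list[str]:
        out = []
        for s in self.intensities.columns:
            comp, t, r = parse_sample_name(s)
            if comp != compartment:
                continue
            if time is not None and abs(t - time) > 1e-9:
                continue
            if replicate is not None and r != replicate:
                continue
            out.append(s)
        return out

    def height(self, feature_id: str, sample_id: str) -> float:
        """Peak height, NaN when absent."""
        return float(self.intensities.at[feature_id, sample_id])

    # -- I/O ---------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        df = self.features.copy()
        df = pd.concat([df.set_index("feature_id"), self.intensities], axis=1)
        df.index.name = "feature_id"
        df.to_csv(path, float_format="%.17g")

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTable":
        import csv

        with open(path, newline="") as fh:
            cols = next(csv.reader(fh))
        if cols[:3] != ["feature_id", "mz", "rt"]:
            raise ValueError("malformed header: expected feature_id, mz, rt, <samples...>")
        seen: set[str] = set()
        for c in cols[3:]:
            if c in seen:
                raise ValueError(f"duplicate sample column: {c!r}")
            seen.add(c)
        df = pd.read_csv(path, float_precision="round_trip")
        feats = df[["feature_id", "mz", "rt"]].copy()
        inten = df.drop(columns=["mz", "rt"]).set_index("feature_id")
        for c in inten.columns:
            if not pd.api.types.is_numeric_dtype(inten[c]):
                raise ValueError(f"non-numeric intensity in column {c!r}")
        return cls(features=feats, intensities=inten.astype(float))


class TargetList(BaseModel):
    """Compound specs to match, with m/z (ppm) and RT tolerances."""

    entries: list[CompoundSpec]
    ppm_tol: float = Field(default=5.0, gt=0)
    rt_tol: float = Field(default=0.1, gt=0, description="min")

    def write(self, path: str | Path) -> None:
        rows = [
            (c.id, c.name, c.mz, c.rt, c.mw, c.compound_class.value, c.initial_donor_conc)
            for c in self.entries
        ]
        pd.DataFrame(
            rows, columns=["id", "name", "mz", "rt", "mw", "class", "initial_conc_uM"]
        ).to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path, ppm_tol: float = 5.0, rt_tol: float = 0.1) -> "TargetList":
        df = pd.read_csv(path)
        entries = [
            CompoundSpec(
                id=str(r["id"]),
                name=str(r.get("name", "")),
                mz=float(r["mz"]),
                rt=float(r["rt"]),
                mw=float(r["mw"]),
                compound_class=str(r["class"]),
                initial_donor_conc=float(r["initial_conc_uM"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(entries=entries, ppm_tol=ppm_tol, rt_tol=rt_tol)


def match_targets(table: FeatureTable, targets: TargetList) -> dict[str, str | None]:
    """Assign each target compound to at most one feature.

    A feature is eligible when |dm/z|/mz <= ppm_tol*1e-6 and |dRT| <= rt_tol.
    Among eligible features the smallest ppm error wins, ties broken by
    smallest |dRT|.  Assignment is greedy over all (compound, feature)
    candidates ordered by ppm error, so each feature quantifies at most one
    compound (prevents one peak standing in for two isomers).
    """
    if len(table.features) == 0:
        raise ValueError("empty feature table")
    mz = table.features["mz"].to_numpy()
    rt = table.features["rt"].to_numpy()
    fids = table.features["feature_id"].to_numpy()

    candidates = []  # (ppm_err, rt_err, compound_id, feature_id)
    for spec in targets.entries:
        ppm_err = np.abs(mz - spec.mz) / spec.mz * 1e6
        rt_err = np.abs(rt - spec.rt)
        ok = (ppm_err <= targets.ppm_tol) & (rt_err <= targets.rt_tol)
        for i in np.flatnonzero(ok):
            candidates.append((float(ppm_err[i]), float(rt_err[i]), spec.id, str(fids[i])))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

    matches: dict[str, str | None] = {spec.id: None for spec in targets.entries}
    used: set[str] = set()
    for _ppm, _rt, cid, fid in candidates:
        if matches[cid] is not None or fid in used:
            continue
        matches[cid] = fid
        used.add(fid)
    return matches


@dataclass
class InterferenceFlag:
    compound_id: str
    flagged: bool
    blank_mean: float
    membrane_mean: float
    detected_in_membrane: bool = True


def check_blank_interference(
    table: FeatureTable,
    matches: dict[str, str | None],
    blank_ratio_max: float = 0.1,
) -> dict[str, InterferenceFlag]:
    """Flag compounds whose blank-membrane signal rivals the membrane signal.

    A compound is flagged when mean blank-membrane height exceeds
    ``blank_ratio_max`` times the mean membrane height; flagged compounds
    should be excluded from membrane ratios downstream.  Without blank
    samples a warning is issued and nothing is flagged.
    """
    import warnings

    blanks = table.sample_ids("blank_membrane")
    membranes = table.sample_ids("membrane")
    flags: dict[str, InterferenceFlag] = {}
    if not blanks:
        warnings.warn("no blank_membrane samples: interference not assessable", stacklevel=2)
    for cid, fid in matches.items():
        if fid is None:
            flags[cid] = InterferenceFlag(cid, False, np.nan, np.nan, False)
            continue
        mem = np.array([table.height(fid, s) for s in membranes]) if membranes else np.array([])
        mem_mean = float(np.nansum(mem) / len(mem)) if len(mem) else np.nan
        detected = len(mem) > 0 and np.any(np.isfinite(mem))
        if not blanks or not detected:
            flags[cid] = InterferenceFlag(cid, False, 0.0 if blanks else np.nan, mem_mean, detected)
            continue
        blk = np.array([table.height(fid, s) for s in blanks])
        blk_mean = float(np.nansum(blk) / len(blk))
        flags[cid] = InterferenceFlag(
            cid, blk_mean > blank_ratio_max * mem_mean, blk_mean, mem_mean, True
        )
    return flags
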