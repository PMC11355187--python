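"""Longitudinal QC registry: per-exposure records, data sets, cohorts.

Terminology follows fleet-surveillance practice: a *data set* is the
longitudinal series of exposures from one radiography-unit/detector/setup
combination; a *cohort* groups data sets acquired under exactly identical
conditions (image type, grid, AEC, collimation, SID, detector position).
Storage is plain CSV plus a JSON manifest so registries diff cleanly and
round-trip byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .iq_metrics import IQResult, METRIC_COLUMNS
from .metadata import AcquisitionSetup, ExposureMetadata

__all__ = [
    "ExposureRecord",
    "DataSet",
    "Cohort",
    "QCRegistry",
    "summarize_metrics",
    "export_running_chart",
]

CHART_COLUMNS = ("timestamp",) + METRIC_COLUMNS + ("kvp", "mas", "flags")


@dataclass(frozen=True)
class ExposureRecord:
    dataset_id: str
    timestamp: str  # ISO 8601
    iq: IQResult
    setup: AcquisitionSetup
    meta: ExposureMetadata | None = None
    source_file: str = ""


@dataclass
class DataSet:
    dataset_id: str
    setup: AcquisitionSetup
    unit_label: str = ""
    detector_label: str = ""
    records: list[ExposureRecord] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class Cohort:
    cohort_id: int
    setup_key: tuple
    member_dataset_ids: tuple[str, ...]
    n_exposures: int


class QCRegistry:
    """In-memory registry of data sets, persistable to a CSV directory."""

    def __init__(self) -> None:
        self.datasets: dict[str, DataSet] = {}

    # ------------------------------------------------------------------
    def add_exposure(self, record: ExposureRecord) -> None:
        """Append a record under its data set (created on first sight).

        Idempotent on identical (dataset_id, source_file) pairs; a setup
        conflicting with the data set's registered setup is an error --
        changed conditions require a new data set.
        """
        ds = self.datasets.get(record.dataset_id)
        if ds is None:
            ds = DataSet(dataset_id=record.dataset_id, setup=record.setup)
            self.datasets[record.dataset_id] = ds
        elif ds.setup != record.setup:
            raise ValueError(
                f"setup drift for data set {record.dataset_id}: register a new data set")
        if record.source_file and any(r.source_file == record.source_file
                                      for r in ds.records):
            return
        ds.records.append(record)
        ds.records.sort(key=lambda r: r.timestamp)

    def exclude(self, dataset_id: str, reason: str) -> None:
        """Manually exclude a data set from statistics (reason mandatory)."""
        if not reason:
            raise ValueError("exclusion requires a non-empty reason")
        self.datasets[dataset_id].excluded = True
        self.datasets[dataset_id].exclusion_reason = reason

    @property
    def n_exposures(self) -> int:
        return sum(len(ds.records) for ds in self.datasets.values())

    def all_records(self, include_excluded: bool = True) -> list[ExposureRecord]:
        out = []
        for ds in sorted(self.datasets.values(), key=lambda d: d.dataset_id):
            if ds.excluded and not include_excluded:
                continue
            out.extend(ds.records)
        return out

    # ------------------------------------------------------------------
    def cluster_cohorts(self) -> list[Cohort]:
        """Group non-excluded data sets by exact setup-key equality.

        Cohort numbering is deterministic: cohorts are ordered by sorted
        setup key and numbered from 1.
        """
        groups: dict[tuple, list[DataSet]] = {}
        for ds in self.datasets.values():
            if ds.excluded:
                continue
            groups.setdefault(ds.setup.setup_key, []).append(ds)
        if not groups:
            raise ValueError("no non-excluded data sets to cluster")
        cohorts = []
        for i, key in enumerate(sorted(groups, key=lambda k: tuple(map(str, k))),
                                start=1):
            members = sorted(groups[key], key=lambda d: d.dataset_id)
            cohorts.append(Cohort(
                cohort_id=i, setup_key=key,
                member_dataset_ids=tuple(d.dataset_id for d in members),
                n_exposures=sum(len(d.records) for d in members)))
        return cohorts

    # ------------------------------------------------------------------
    def save(self, directory) -> None:
        """Persist as ``datasets/<id>.csv`` plus ``manifest.json``."""
        root = Path(directory)
        (root / "datasets").mkdir(parents=True, exist_ok=True)
        manifest = {"datasets": []}
        for ds_id in sorted(self.datasets):
            ds = self.datasets[ds_id]
            export_running_chart(ds, root / "datasets" / f"{ds_id}.csv")
            manifest["datasets"].append({
                "dataset_id": ds.dataset_id,
                "unit_label": ds.unit_label,
                "detector_label": ds.detector_label,
                "excluded": ds.excluded,
                "exclusion_reason": ds.exclusion_reason,
                "setup": {
                    "image_type": ds.setup.image_type,
                    "grid": ds.setup.grid, "aec": ds.setup.aec,
                    "collimation": ds.setup.collimation,
                    "sid_cm": ds.setup.sid_cm,
                    "detector_position": ds.setup.detector_position,
                    "protocol": ds.setup.protocol,
                },
            })
        with open(root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory) -> "QCRegistry":
        root = Path(directory)
        with open(root / "manifest.json") as fh:
            manifest = json.load(fh)
        reg = cls()
        for entry in manifest["datasets"]:
            setup = AcquisitionSetup(**entry["setup"])
            ds = DataSet(dataset_id=entry["dataset_id"], setup=setup,
                         unit_label=entry["unit_label"],
                         detector_label=entry["detector_label"],
                         excluded=entry["excluded"],
                         exclusion_reason=entry["exclusion_reason"])
            frame = pd.read_csv(root / "datasets" / f"{entry['dataset_id']}.csv",
                                float_precision="round_trip")
            for _, row in frame.iterrows():
                iq = IQResult(
                    snr=row["SNR"], sdnr=row["SDNR"],
                    hmtf50=_maybe(row["HMTF50"]), hmtf20=_maybe(row["HMTF20"]),
                    hmtf10=_maybe(row["HMTF10"]), vmtf50=_maybe(row["VMTF50"]),
                    vmtf20=_maybe(row["VMTF20"]), vmtf10=_maybe(row["VMTF10"]),
                    dprime_03=row["DPRIME_03"], dprime_40=row["DPRIME_40"],
                    qc_flags=tuple(str(row["flags"]).split(";"))
                    if isinstance(row["flags"], str) and row["flags"] else ())
                meta = None
                rec = ExposureRecord(dataset_id=ds.dataset_id,
                                     timestamp=str(row["timestamp"]), iq=iq,
                                     setup=setup, meta=meta,
                                     source_file=str(row.get("source_file", "")))
                ds.records.append(rec)
            reg.datasets[ds.dataset_id] = ds
        return reg


def _maybe(value):
    return None if pd.isna(value) else float(value)


def export_running_chart(dataset: DataSet, path) -> None:
    """Write one data set's longitudinal chart as CSV (time-ordered rows)."""
    if not dataset.records:
        raise ValueError(f"data set {dataset.dataset_id} is empty")
    rows = []
    for rec in dataset.records:
        row = {"timestamp": rec.timestamp}
        row.update(rec.iq.to_dict())
        row["kvp"] = rec.meta.kvp if rec.meta else None
        row["mas"] = rec.meta.mas if rec.meta else None
        row["flags"] = ";".join(rec.iq.qc_flags)
        row["source_file"] = rec.source_file
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CHART_COLUMNS) + ["source_file"])
    frame.to_csv(path, index=False)


def summarize_metrics(records, group: str = "all") -> pd.DataFrame:
    """Fleet summary table: per metric min, max, median, mean, sample SD.

    ``group`` selects all records or the processed / raw stratum (by the
    acquisition setup's image type).  Rows follow the canonical metric
    order; columns are Min/Max/Median/Mean/StDev.
    """
    if group not in ("all", "processed", "raw"):
        raise ValueError("group must be all|processed|raw")
    if group != "all":
        records = [r for r in records if r.setup.image_type == group]
    if len(records) == 0:
        warnings.warn(f"empty group {group!r}: summary omitted", stacklevel=2)
        return pd.DataFrame(columns=["Min", "Max", "Median", "Mean", "StDev"])
    if len(records) == 1:
        raise ValueError("sample SD undefined for a single record")
    table = {}
    for metric in METRIC_COLUMNS:
        vals = np.array([r.iq.to_dict()[metric] for r in records], dtype=float)
        vals = vals[np.isfinite(vals)]
        table[metric] = {
            "Min": vals.min(), "Max": vals.max(),
            "Median": float(np.median(vals)), "Mean": vals.mean(),
            "StDev": vals.std(ddof=1),
        }
    return pd.DataFrame(table).T[["Min", "Max", "Median", "Mean", "StDev"]]
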