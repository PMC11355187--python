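"""Exposure-metadata harvesting from DICOM headers, pathology-tolerant.

Vendor DICOM dialects in real fleets omit exposure index / entrance dose,
store the exposure index under non-standard addresses, round mAs to integers
or zero it outright, and report organ dose as a constant zero.  The harvester
therefore walks ordered candidate tag lists (standard address first), never
raises on absent optional tags, and reports everything it could not trust as
flags rather than guessing.  EI and entrance dose are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pydicom
from pydicom.errors import InvalidDicomError

__all__ = [
    "ExposureMetadata",
    "AcquisitionSetup",
    "harvest_exposure_metadata",
    "classify_image_type",
    "EI_TAG_CANDIDATES",
    "MAS_TAG_CANDIDATES",
]

#: ordered candidate addresses for the exposure index: the standard tag
#: first, then the alternates the synthetic writer's dialects can emit
EI_TAG_CANDIDATES: tuple[tuple[int, int], ...] = (
    (0x0018, 0x1411),  # ExposureIndex (standard)
    (0x0018, 0x1405),  # RelativeXRayExposure (vendor alternate)
)
#: mAs candidates: microamp-seconds first (sub-mAs precision), then mAs
MAS_TAG_CANDIDATES: tuple[tuple[int, int], ...] = (
    (0x0018, 0x1153),  # ExposureInuAs
    (0x0018, 0x1152),  # Exposure (mAs, integer VR)
)
TAG_ENTRANCE_DOSE = (0x0040, 0x8302)
TAG_ORGAN_DOSE = (0x0040, 0x0316)

VALID_DETECTOR_POSITIONS = ("CB", "TB", "free")


@dataclass(frozen=True)
class ExposureMetadata:
    vendor: str | None
    model: str | None
    kvp: float | None
    mas: float | None
    entrance_dose: float | None
    exposure_index: float | None
    organ_dose: float | None
    image_type: str  # raw | processed | unknown
    flags: frozenset[str]

    def is_flagged(self, flag: str) -> bool:
        return flag in self.flags


@dataclass(frozen=True)
class AcquisitionSetup:
    """Acquisition conditions that define a surveillance cohort."""

    image_type: str = "raw"
    grid: bool = False
    aec: bool = False
    collimation: bool = True
    sid_cm: int | None = 100
    detector_position: str = "TB"
    protocol: str = "abdomen"
    receptor_dims_cm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.image_type not in ("raw", "processed"):
            raise ValueError("image_type must be raw|processed")
        if self.detector_position not in VALID_DETECTOR_POSITIONS:
            raise ValueError(f"detector_position must be one of {VALID_DETECTOR_POSITIONS}")
        if self.sid_cm is not None and not 80 <= self.sid_cm <= 250:
            raise ValueError("sid_cm must lie in [80, 250]")

    @property
    def setup_key(self) -> tuple:
        """Exact-match key used for cohort clustering (SID as integer cm)."""
        return (self.image_type, self.grid, self.aec, self.collimation,
                int(self.sid_cm) if self.sid_cm is not None else None,
                self.detector_position)


def _read(path_or_ds) -> pydicom.Dataset:
    if isinstance(path_or_ds, pydicom.Dataset):
        return path_or_ds
    try:
        return pydicom.dcmread(str(path_or_ds))
    except (InvalidDicomError, OSError) as exc:
        raise ValueError(f"not a readable DICOM file: {path_or_ds}") from exc


def _first_tag(ds: pydicom.Dataset, candidates: Iterable[tuple[int, int]]):
    for i, tag in enumerate(candidates):
        if tag in ds and ds[tag].value not in (None, ""):
            return i, ds[tag].value
    return None, None


def classify_image_type(path_or_ds) -> str:
    """Map DICOM presentation intent to raw/processed; report, never guess."""
    ds = _read(path_or_ds)
    intent = str(getattr(ds, "PresentationIntentType", "")).upper()
    if "FOR PROCESSING" in intent:
        return "raw"
    if "FOR PRESENTATION" in intent:
        return "processed"
    return "unknown"


def harvest_exposure_metadata(path_or_ds) -> ExposureMetadata:
    """Extract exposure metadata from a DICOM header, flagging pathologies.

    Total over conformant files: any readable DICOM yields a (possibly
    heavily flagged) record.  Flags: ``missing_ei``, ``missing_ed``,
    ``mas_zero``, ``mas_rounded_suspect`` (heuristic: integer-valued mAs),
    ``organ_dose_zero``, ``ei_nonstandard_tag``.
    """
    ds = _read(path_or_ds)
    flags: set[str] = set()

    vendor = getattr(ds, "Manufacturer", None)
    model = getattr(ds, "ManufacturerModelName", None)
    kvp = getattr(ds, "KVP", None)
    kvp = float(kvp) if kvp not in (None, "") else None

    mas = None
    i, raw_mas = _first_tag(ds, MAS_TAG_CANDIDATES)
    if raw_mas is not None:
        mas = float(raw_mas) / 1000.0 if MAS_TAG_CANDIDATES[i] == (0x0018, 0x1153) \
            else float(raw_mas)
        if mas == 0:
            flags.add("mas_zero")
        elif float(mas).is_integer():
            flags.add("mas_rounded_suspect")  # heuristic, not proof

    i, raw_ei = _first_tag(ds, EI_TAG_CANDIDATES)
    ei = float(raw_ei) if raw_ei is not None else None
    if ei is None:
        flags.add("missing_ei")
    elif i > 0:
        flags.add("ei_nonstandard_tag")

    ed = None
    if TAG_ENTRANCE_DOSE in ds and ds[TAG_ENTRANCE_DOSE].value not in (None, ""):
        ed = float(ds[TAG_ENTRANCE_DOSE].value)
    else:
        flags.add("missing_ed")

    organ = None
    if TAG_ORGAN_DOSE in ds and ds[TAG_ORGAN_DOSE].value not in (None, ""):
        organ = float(ds[TAG_ORGAN_DOSE].value)
        if organ == 0:
            flags.add("organ_dose_zero")

    return ExposureMetadata(
        vendor=str(vendor) if vendor else None,
        model=str(model) if model else None,
        kvp=kvp, mas=mas, entrance_dose=ed, exposure_index=ei,
        organ_dose=organ, image_type=classify_image_type(ds),
        flags=frozenset(flags))
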