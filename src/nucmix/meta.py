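"""Coordinate-based meta-analysis of reported STN/SN activation foci.

Parses the packaged literature table (52 BOLD fMRI studies, one row per
reported activation coordinate), harmonizes coordinate spaces, and
compares reported foci against reference centers of mass of the nuclei:
signed per-axis deviations, Euclidean distances, smoothing-kernel and
voxel-size summaries, and coordinate-vs-kernel correlations.

Reference centers of mass can come from a synthetic probabilistic atlas,
from real probabilistic masks on disk, or be supplied directly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .atlas import center_of_mass_mm

__all__ = [
    "STRUCTURES",
    "STRUCTURE_TO_REFERENCE",
    "TAL2MNI",
    "FocusRecord",
    "ReferenceCOM",
    "packaged_foci_path",
    "load_foci",
    "tal_to_mni",
    "mni_to_tal",
    "assign_hemisphere",
    "deviation_stats",
    "kernel_summary",
    "voxel_summary",
    "coord_kernel_correlation",
    "com_separation",
    "roi_volume_ratio",
    "reference_coms_from_cohort",
    "load_reference_coms",
    "save_reference_coms",
]

#: Structure labels as reported in the literature table.
STRUCTURES = ("STN", "SN", "SN/VTA", "SN/STN")

#: Which nucleus's center of mass each reported label is compared against:
#: STN foci against the STN mask, everything else against the SN mask.
STRUCTURE_TO_REFERENCE = {"STN": "STN", "SN": "SN", "SN/VTA": "SN", "SN/STN": "SN"}

#: Talairach -> MNI/ICBM affine: the pooled ("other") tal2icbm matrix of
#: Lancaster et al. (2007), Hum Brain Mapp 28:1194-1205 (inverse of their
#: pooled icbm2tal transform).
TAL2MNI = np.array(
    [
        [0.9357, 0.0029, -0.0072, -1.0423],
        [-0.0065, 0.9396, -0.0726, -1.3940],
        [0.0103, 0.0752, 0.8967, 3.6475],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

_MISSING = {"N.S.", "n.s.", "-", ""}

# fixture manifest: the loader validates against these
_EXPECTED_N_ROWS = 122
_EXPECTED_N_STUDIES = 52


@dataclass(frozen=True)
class FocusRecord:
    """One reported activation coordinate with its study metadata.

    Coordinates are MNI mm (Talairach-reported foci were converted at
    transcription time).  ``None`` marks values the study did not report.
    """

    study_id: str
    task: str
    structure: str
    space: str
    x: float | None
    y: float | None
    z: float | None
    fwhm: float | None
    voxel_volume: float | None
    field_strength: float | None
    slice_gap: bool = False
    outside_figure: bool = False

    @property
    def has_coordinate(self) -> bool:
        return self.x is not None and self.y is not None and self.z is not None

    @property
    def coordinate(self) -> np.ndarray:
        if not self.has_coordinate:
            raise ValueError(f"record of {self.study_id} has no coordinate")
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class ReferenceCOM:
    """Reference center of mass of one nucleus in one hemisphere (MNI mm)."""

    structure: str
    hemisphere: str
    coordinate: tuple[float, float, float]
    source: str = "user_supplied"

    def __post_init__(self) -> None:
        if self.structure not in ("STN", "SN"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        coord = tuple(float(c) for c in self.coordinate)
        if self.hemisphere == "L" and coord[0] >= 0:
            raise ValueError(f"left-hemisphere COM must have x < 0, got {coord}")
        if self.hemisphere == "R" and coord[0] < 0:
            raise ValueError(f"right-hemisphere COM must have x >= 0, got {coord}")
        object.__setattr__(self, "coordinate", coord)


def packaged_foci_path() -> Path:
    """Path of the shipped literature-foci table."""
    return Path(resources.files("nucmix").joinpath("data/table1_foci.csv"))


def _parse_float(cell: str) -> float | None:
    cell = cell.strip()
    if cell in _MISSING:
        return None
    return float(cell.replace(",", "."))


def load_foci(path=None) -> list[FocusRecord]:
    """Load focus records from a CSV table (default: the packaged fixture).

    Unspecified cells ("N.S.", "-") become ``None``; rows without
    coordinates are retained (they still inform the kernel and voxel
    summaries).  When the packaged fixture is loaded, row and study
    counts are validated against the fixture manifest.
    """
    packaged = path is None
    path = packaged_foci_path() if packaged else Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"study_id", "structure", "x_mm", "y_mm", "z_mm", "fwhm_mm"}
        missing_cols = required - set(reader.fieldnames or [])
        if missing_cols:
            raise ValueError(f"foci table missing columns: {sorted(missing_cols)}")
        for i, row in enumerate(reader, start=2):
            structure = row["structure"].strip()
            if structure not in STRUCTURES:
                raise ValueError(f"row {i}: unknown structure label {structure!r}")
            try:
                x, y, z = (_parse_float(row[c]) for c in ("x_mm", "y_mm", "z_mm"))
                fwhm = _parse_float(row["fwhm_mm"])
                vol = _parse_float(row.get("voxel_volume_mm3", ""))
                tesla = _parse_float(row.get("field_strength_t", ""))
            except ValueError as exc:
                raise ValueError(f"row {i}: non-numeric value ({exc})") from exc
            records.append(
                FocusRecord(
                    study_id=row["study_id"].strip(),
                    task=row.get("task", "").strip(),
                    structure=structure,
                    space=row.get("space", "MNI").strip() or "MNI",
                    x=x,
                    y=y,
                    z=z,
                    fwhm=fwhm,
                    voxel_volume=vol,
                    field_strength=tesla,
                    slice_gap=row.get("slice_gap", "0").strip() == "1",
                    outside_figure=row.get("outside_figure", "0").strip() == "1",
                )
            )
    if packaged:
        n_studies = len({r.study_id for r in records})
        if len(records) != _EXPECTED_N_ROWS or n_studies != _EXPECTED_N_STUDIES:
            raise ValueError(
                f"packaged fixture corrupt: {len(records)} rows / {n_studies} studies "
                f"(expected {_EXPECTED_N_ROWS} / {_EXPECTED_N_STUDIES})"
            )
    return records


def tal_to_mni(coord) -> np.ndarray:
    """Talairach -> MNI via the pooled Lancaster affine."""
    coord = np.asarray(coord, dtype=float)
    if coord.shape != (3,) or not np.all(np.isfinite(coord)):
        raise ValueError("coordinate must be a finite 3-vector")
    return TAL2MNI[:3, :3] @ coord + TAL2MNI[:3, 3]


def mni_to_tal(coord) -> np.ndarray:
    """MNI -> Talairach (inverse of :func:`tal_to_mni`)."""
    coord = np.asarray(coord, dtype=float)
    if coord.shape != (3,) or not np.all(np.isfinite(coord)):
        raise ValueError("coordinate must be a finite 3-vector")
    return np.linalg.solve(TAL2MNI[:3, :3], coord - TAL2MNI[:3, 3])


def assign_hemisphere(record_or_x) -> str:
    """Hemisphere of a focus: x < 0 is left, x >= 0 is right.

    Midline foci (x = 0) are assigned to the right by convention.
    """
    x = record_or_x.x if isinstance(record_or_x, FocusRecord) else record_or_x
    if x is None:
        raise ValueError("cannot assign hemisphere without an x coordinate")
    return "L" if x < 0 else "R"


def _ref_lookup(refs) -> dict:
    return {(r.structure, r.hemisphere): np.asarray(r.coordinate) for r in refs}


def deviation_stats(records, refs) -> pd.DataFrame:
    """Per structure-label x hemisphere deviation of foci from reference COMs.

    Signed deviations are focus minus COM per axis (positive x: more to
    the right; positive y: more anterior; positive z: more superior);
    ``total`` is the per-focus Euclidean distance.  Means and sample SDs
    are taken over foci; study counts are deduplicated.  Rows without
    coordinates are ignored.
    """
    lookup = _ref_lookup(refs)
    rows = []
    with_coords = [r for r in records if r.has_coordinate]
    groups: dict[tuple[str, str], list[FocusRecord]] = {}
    for rec in with_coords:
        groups.setdefault((rec.structure, assign_hemisphere(rec)), []).append(rec)
    for (structure, hemi), recs in sorted(groups.items()):
        ref_structure = STRUCTURE_TO_REFERENCE[structure]
        key = (ref_structure, hemi)
        if key not in lookup:
            raise ValueError(f"missing reference COM for {ref_structure} {hemi}")
        com = lookup[key]
        deltas = np.array([rec.coordinate - com for rec in recs])
        totals = np.linalg.norm(deltas, axis=1)
        n = len(recs)
        sd = lambda a: float(np.std(a, ddof=1)) if n > 1 else np.nan  # noqa: E731
        rows.append(
            {
                "structure_group": structure,
                "hemisphere": hemi,
                "n_coordinates": n,
                "n_studies": len({rec.study_id for rec in recs}),
                "mean_dx": float(deltas[:, 0].mean()),
                "sd_dx": sd(deltas[:, 0]),
                "mean_dy": float(deltas[:, 1].mean()),
                "sd_dy": sd(deltas[:, 1]),
                "mean_dz": float(deltas[:, 2].mean()),
                "sd_dz": sd(deltas[:, 2]),
                "mean_total": float(totals.mean()),
                "sd_total": sd(totals),
            }
        )
    return pd.DataFrame(rows)


def _per_study_values(records, attr: str) -> dict[str, float]:
    """Mean of a per-row numeric field within each study (missing excluded)."""
    per_study: dict[str, list[float]] = {}
    for rec in records:
        val = getattr(rec, attr)
        if val is not None:
            per_study.setdefault(rec.study_id, []).append(float(val))
    return {sid: float(np.mean(vals)) for sid, vals in per_study.items()}


def kernel_summary(records) -> dict:
    """Smoothing-kernel summary across studies.

    Studies reporting several kernels contribute their within-study mean
    to the mean/median; the modal value is the most common individual
    kernel size, and ``n_studies_mode`` counts studies reporting *any*
    kernel of that size.
    """
    if not records:
        raise ValueError("no records")
    per_study = _per_study_values(records, "fwhm")
    if not per_study:
        raise ValueError("no study reports a smoothing kernel")
    study_kernels: dict[str, set] = {}
    for rec in records:
        if rec.fwhm is not None:
            study_kernels.setdefault(rec.study_id, set()).add(float(rec.fwhm))
    counts: dict[float, int] = {}
    for kernels in study_kernels.values():
        for k in kernels:
            counts[k] = counts.get(k, 0) + 1
    mode = max(sorted(counts), key=lambda k: counts[k])
    values = np.array(list(per_study.values()))
    return {
        "n_studies_total": len({r.study_id for r in records}),
        "n_studies_reporting": len(per_study),
        "mean_fwhm_mm": float(values.mean()),
        "median_fwhm_mm": float(np.median(values)),
        "modal_fwhm_mm": float(mode),
        "n_studies_mode": int(counts[mode]),
    }


def voxel_summary(records) -> dict:
    """Functional voxel-volume summary across studies (per-study means)."""
    if not records:
        raise ValueError("no records")
    per_study = _per_study_values(records, "voxel_volume")
    values = np.array(list(per_study.values()))
    return {
        "n_studies_total": len({r.study_id for r in records}),
        "n_studies_reporting": len(per_study),
        "mean_voxel_volume_mm3": float(values.mean()) if len(values) else np.nan,
        "median_voxel_volume_mm3": float(np.median(values)) if len(values) else np.nan,
        "sd_voxel_volume_mm3": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
        "min_voxel_volume_mm3": float(values.min()) if len(values) else np.nan,
        "max_voxel_volume_mm3": float(values.max()) if len(values) else np.nan,
    }


def coord_kernel_correlation(records, structures, axis: str) -> tuple[float, int, float]:
    """Pearson correlation between a coordinate axis and kernel FWHM.

    ``structures`` selects which reported labels enter (e.g. all
    SN-type labels); pairs require both the coordinate and the kernel.
    Returns ``(r, df, p)`` with ``df = n - 2``.
    """
    if axis not in ("x", "y", "z"):
        raise ValueError(f"axis must be x, y or z, got {axis!r}")
    pairs = [
        (getattr(rec, axis), rec.fwhm)
        for rec in records
        if rec.structure in structures and getattr(rec, axis) is not None and rec.fwhm is not None
    ]
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(pairs)}")
    coords, fwhms = map(np.asarray, zip(*pairs))
    if np.ptp(fwhms) == 0:
        raise ValueError("kernel FWHM is constant in the selected group")
    r, p = stats.pearsonr(coords, fwhms)
    return float(r), len(pairs) - 2, float(p)


def com_separation(refs) -> dict[str, float]:
    """Euclidean STN-SN center-of-mass distance per hemisphere (mm)."""
    lookup = _ref_lookup(refs)
    out = {}
    for hemi in ("L", "R"):
        if ("STN", hemi) in lookup and ("SN", hemi) in lookup:
            out[hemi] = float(np.linalg.norm(lookup[("STN", hemi)] - lookup[("SN", hemi)]))
    if not out:
        raise ValueError("need STN and SN reference COMs in at least one hemisphere")
    return out


def roi_volume_ratio(roi_volume: float, nucleus_volume: float) -> float:
    """How many times larger an ROI is than the nucleus it targets."""
    if roi_volume <= 0 or nucleus_volume <= 0:
        raise ValueError("volumes must be positive")
    return roi_volume / nucleus_volume


def reference_coms_from_cohort(cohort) -> list[ReferenceCOM]:
    """Probability-weighted atlas COMs of a synthetic cohort."""
    from .anatomy import build_probabilistic_atlas  # deferred: avoids import cycle

    refs = []
    for structure in ("STN", "SN"):
        for hemi in ("L", "R"):
            atlas = build_probabilistic_atlas(cohort, structure, hemi)
            refs.append(
                ReferenceCOM(
                    structure=structure,
                    hemisphere=hemi,
                    coordinate=tuple(center_of_mass_mm(atlas)),
                    source="synthetic_atlas",
                )
            )
    return refs


def load_reference_coms(path) -> list[ReferenceCOM]:
    """Read reference COMs from YAML: ``{STN: {L: [x,y,z], R: ...}, SN: ...}``."""
    raw = yaml.safe_load(Path(path).read_text())
    refs = []
    for structure, hemis in raw.items():
        for hemi, coord in hemis.items():
            refs.append(
                ReferenceCOM(
                    structure=structure,
                    hemisphere=hemi,
                    coordinate=tuple(float(c) for c in coord),
                    source="external_file",
                )
            )
    return refs


def save_reference_coms(refs, path) -> None:
    out: dict[str, dict[str, list[float]]] = {}
    for r in refs:
        out.setdefault(r.structure, {})[r.hemisphere] = [float(c) for c in r.coordinate]
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
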