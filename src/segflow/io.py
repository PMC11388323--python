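"""File formats: NIfTI volumes, TSV tables, WAV audio, JSON metadata.

Conventions stated in every output: voxel indices 0-based, times in
seconds, scan index 0-based at frame onset.  TR is recorded in the NIfTI
time-axis pixdim on write and read back from there.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .regressor import MarkerSet
from .synthetic import GroundTruth
from .volumes import VolumeSeries

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_markers",
    "write_markers",
    "read_regressor_tsv",
    "write_regressor_tsv",
    "read_timecourses",
    "write_timecourses",
    "read_wav",
    "ground_truth_to_json",
    "ground_truth_from_json",
]


def write_volume(vol: VolumeSeries, path: "str | Path") -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (vol.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_volume(
    path: "str | Path",
    mask: np.ndarray | None = None,
    tr: float | None = None,
    subject_id: str = "sub-00",
    group: str = "none",
) -> VolumeSeries:
    """Load a 4-D NIfTI; TR comes from the header unless supplied."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got {data.ndim}-D")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ValueError(f"{path}: TR missing from header and not supplied")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume spatial shape "
            f"{data.shape[:3]}"
        )
    return VolumeSeries(
        data=data, mask=mask, tr=tr, subject_id=subject_id, group=group,
        affine=img.affine,
    )


def write_mask(mask: np.ndarray, path: "str | Path",
               affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), affine if affine is not None
                          else np.eye(4))
    nib.save(img, str(path))


def read_mask(path: "str | Path") -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_markers(markers: MarkerSet, path: "str | Path") -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def read_markers(path: "str | Path", duration: float) -> MarkerSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return MarkerSet.from_frame(df, duration=duration)


def write_regressor_tsv(values: np.ndarray, path: "str | Path") -> None:
    pd.DataFrame(
        {"scan_index": np.arange(len(values)), "value": np.asarray(values)}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_regressor_tsv(path: "str | Path") -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.sort_values("scan_index")["value"].to_numpy(dtype=float)


def write_timecourses(
    tcs: np.ndarray, subject_ids: list[str], path: "str | Path"
) -> None:
    """(n_subjects, n_components, n_scans) -> long TSV."""
    n_subj, n_comp, n_scans = tcs.shape
    rows = {
        "subject_id": np.repeat(subject_ids, n_comp * n_scans),
        "component": np.tile(np.repeat(np.arange(n_comp), n_scans), n_subj),
        "scan_index": np.tile(np.arange(n_scans), n_subj * n_comp),
        "value": tcs.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timecourses(path: "str | Path") -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ids = list(dict.fromkeys(df["subject_id"]))
    n_comp = df["component"].nunique()
    n_scans = df["scan_index"].nunique()
    tcs = np.empty((len(ids), n_comp, n_scans))
    for s, pid in enumerate(ids):
        sub = df[df["subject_id"] == pid]
        for c in range(n_comp):
            tcs[s, c] = (
                sub[sub["component"] == c].sort_values("scan_index")["value"]
                .to_numpy(dtype=float)
            )
    return tcs, [str(i) for i in ids]


def read_wav(path: "str | Path") -> tuple[np.ndarray, float]:
    """Mono waveform (first channel of multi-channel files) and sample rate."""
    from scipy.io import wavfile

    rate, data = wavfile.read(str(path))
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, 0]
    return data, float(rate)


def ground_truth_to_json(truth: GroundTruth, path: "str | Path") -> None:
    payload = {
        "boundary_times_s": truth.boundary_times.tolist(),
        "boundary_salience": truth.boundary_salience.tolist(),
        "lag_weights": truth.lag_weights.tolist(),
        "lags": [-1, 0, 1],
        "coupling_coeff": truth.coupling_coeff,
        "group_gain": truth.group_gain,
        "noise_ar1": truth.noise_ar1,
        "snr": truth.snr,
        "network_sigma_vox": truth.network_sigma_vox,
        "confound_share": truth.confound_share,
        "kde_bandwidth_s": truth.kde_bandwidth,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def ground_truth_from_json(path: "str | Path") -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        boundary_times=np.array(d["boundary_times_s"]),
        boundary_salience=np.array(d["boundary_salience"]),
        lag_weights=np.array(d["lag_weights"]),
        coupling_coeff=d["coupling_coeff"],
        group_gain=d["group_gain"],
        noise_ar1=d["noise_ar1"],
        snr=d["snr"],
        network_sigma_vox=d["network_sigma_vox"],
        confound_share=d["confound_share"],
        kde_bandwidth=d["kde_bandwidth_s"],
    )
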