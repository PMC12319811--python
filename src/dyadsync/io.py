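"""On-disk dataset layout and result writers.

A dataset directory holds one HDF5 container per subject (one group per
ROI with a ``data`` dataset and ``subject_id``/``roi_id`` attributes),
TSV tables for the parcellation, dyads, clips and condition mask, and a
JSON manifest tying them together. All TR indices on disk are 0-based
with half-open ``[start, end)`` intervals. Because the run length after
any trimming varies between acquisitions, T is carried explicitly by the
data rather than assumed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import Dataset, RoiTimeSeries, RunMetadata, ValidationError
from .trajectory import IstsTable

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset in the reference layout; returns the manifest path."""
    out = Path(out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[RoiTimeSeries]] = {}
    for (sid, _), ts in dataset.timeseries.items():
        by_subject.setdefault(sid, []).append(ts)
    for sid in sorted(by_subject):
        with h5py.File(out / "subjects" / f"{sid}.h5", "w") as f:
            for ts in sorted(by_subject[sid], key=lambda t: t.roi_id):
                grp = f.create_group(f"roi_{ts.roi_id:04d}")
                grp.create_dataset("data", data=ts.data)
                grp.attrs["subject_id"] = ts.subject_id
                grp.attrs["roi_id"] = ts.roi_id
    dataset.parcellation.to_csv(out / "parcellation.tsv", sep="\t", index=False)
    dataset.dyads.to_csv(out / "dyads.tsv", sep="\t", index=False)
    manifest = {
        "subjects": {sid: f"subjects/{sid}.h5" for sid in sorted(by_subject)},
        "parcellation": "parcellation.tsv",
        "dyads": "dyads.tsv",
        "n_trs": dataset.n_trs,
    }
    if dataset.metadata.clip_table is not None:
        dataset.metadata.clip_table.to_csv(out / "clips.tsv", sep="\t", index=False)
        manifest["clips"] = "clips.tsv"
    if dataset.metadata.condition_mask is not None:
        dataset.metadata.condition_mask.to_csv(
            out / "condition_mask.tsv", sep="\t", index=False
        )
        manifest["condition_mask"] = "condition_mask.tsv"
    if dataset.ground_truth is not None:
        with open(out / "ground_truth.json", "w") as f:
            json.dump(dataset.ground_truth, f, indent=1, sort_keys=True)
        manifest["ground_truth"] = "ground_truth.json"
    manifest_path = out / MANIFEST_NAME
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest_path


def _require(path: Path) -> Path:
    if not path.exists():
        raise ValidationError(f"missing file: {path}")
    return path


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load and fully validate a dataset from its manifest.

    Every referenced file must exist; dyads must reference known subjects;
    each ROI matrix must satisfy the >=3 voxels / >=3 TRs contract (these
    checks run inside :class:`Dataset`). A validation summary is logged.
    """
    manifest_path = _require(Path(manifest_path))
    root = manifest_path.parent
    with open(manifest_path) as f:
        manifest = json.load(f)
    timeseries: dict[tuple[str, int], RoiTimeSeries] = {}
    for sid, rel in manifest["subjects"].items():
        with h5py.File(_require(root / rel), "r") as hf:
            for name in sorted(hf):
                grp = hf[name]
                ts = RoiTimeSeries(
                    subject_id=str(grp.attrs["subject_id"]),
                    roi_id=int(grp.attrs["roi_id"]),
                    data=np.asarray(grp["data"]),
                )
                if ts.subject_id != sid:
                    raise ValidationError(
                        f"subject container {rel} holds data for {ts.subject_id}"
                    )
                timeseries[(ts.subject_id, ts.roi_id)] = ts
    parcellation = pd.read_csv(_require(root / manifest["parcellation"]), sep="\t")
    dyads = pd.read_csv(_require(root / manifest["dyads"]), sep="\t")
    metadata = RunMetadata()
    if "clips" in manifest:
        metadata.clip_table = pd.read_csv(_require(root / manifest["clips"]), sep="\t")
    if "condition_mask" in manifest:
        metadata.condition_mask = pd.read_csv(
            _require(root / manifest["condition_mask"]), sep="\t"
        )
    ground_truth = None
    if "ground_truth" in manifest:
        with open(_require(root / manifest["ground_truth"])) as f:
            ground_truth = json.load(f)
    dataset = Dataset(
        timeseries=timeseries,
        parcellation=parcellation,
        dyads=dyads,
        metadata=metadata,
        ground_truth=ground_truth,
    )
    logger.info("loaded dataset: %s", dataset.summary())
    return dataset


def write_results(
    out_dir: str | Path,
    ists_tables: list[IstsTable] | None = None,
    pls_result=None,
    group_tests: pd.DataFrame | None = None,
    summary_extra: dict | None = None,
) -> dict:
    """Write analysis outputs: long-format TSVs plus a JSON run summary.

    Column order is fixed and rows are sorted, so re-running on the same
    inputs reproduces the files byte for byte.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"cannot write to {out}: {exc}")
    summary: dict = {"outputs": []}
    for table in ists_tables or []:
        name = f"ists_{table.scope}.tsv"
        table.to_long().to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        summary["outputs"].append(name)
        if table.whole_brain is not None:
            wb_name = f"whole_brain_{table.scope}.tsv"
            table.whole_brain.rename("mean_ists").rename_axis("dyad_id").reset_index().to_csv(
                out / wb_name, sep="\t", index=False, float_format="%.10g"
            )
            summary["outputs"].append(wb_name)
    if pls_result is not None:
        pls_result.roi_table.to_csv(
            out / "pls_result.tsv", sep="\t", index=False, float_format="%.10g"
        )
        summary["outputs"].append("pls_result.tsv")
        summary["pls"] = {
            "covariance_explained": pls_result.covariance_explained,
            "p_permutation": pls_result.p_permutation,
            "n_significant_rois": int(pls_result.roi_table["fdr_significant"].sum()),
            "n_perm": pls_result.n_perm,
            "n_boot": pls_result.n_boot,
        }
    if group_tests is not None:
        group_tests.to_csv(
            out / "group_tests.tsv", sep="\t", index=False, float_format="%.10g"
        )
        summary["outputs"].append("group_tests.tsv")
    if summary_extra:
        summary.update(summary_extra)
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, sort_keys=True)
    return summary


def read_ists_long(path: str | Path) -> pd.DataFrame:
    """Read a long-format ISTS TSV back into a DataFrame."""
    return pd.read_csv(_require(Path(path)), sep="\t")
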