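"""Result files and the run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Sequence

from tfusim import __version__
from tfusim.acoustic_solver import FieldMaps
from tfusim.coupling_pipeline import ResponseRecord, records_to_dataframe, summarize


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    records: Sequence[ResponseRecord],
    maps: Optional[Dict[str, FieldMaps]],
    out_dir,
    config=None,
) -> dict:
    """Write records.csv, summary.csv and maps.h5; return the manifest.

    The manifest lists every file with its digest, the config hash and
    the tool version, and is itself written as manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    records_csv = out / "records.csv"
    df = records_to_dataframe(records)
    df.to_csv(records_csv, index=False, float_format="%.10g")
    files.append(records_csv)

    if records:
        summary_csv = out / "summary.csv"
        summarize(records).to_csv(summary_csv, index=False, float_format="%.10g")
        files.append(summary_csv)

    if maps:
        import h5py

        maps_h5 = out / "maps.h5"
        with h5py.File(maps_h5, "w") as fh:
            for name, field in maps.items():
                grp = fh.create_group(name)
                grp.attrs["dx"] = field.dx
                grp.create_dataset("max_pressure", data=field.max_pressure)
                grp.create_dataset("avg_intensity", data=field.avg_intensity)
        files.append(maps_h5)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash() if config is not None else None,
        "files": {f.name: _sha256(f) for f in files},
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
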