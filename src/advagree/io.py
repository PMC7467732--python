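"""Response-table CSV round-tripping, external-layout import, run manifests.

The on-disk response table is a UTF-8 comma-separated file with a header row
and the columns of :data:`advagree.cohort.RESPONSE_COLUMNS`; the list of
alternatives is pipe-joined in presentation order. Malformed rows fail loudly
with their line number.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from advagree.cohort import ALTERNATIVES_SEP, RESPONSE_COLUMNS

__all__ = [
    "read_response_table",
    "write_response_table",
    "import_osf_layout",
    "write_manifest",
]


class ResponseTableError(ValueError):
    """Raised when a response-table file violates the schema."""


def read_response_table(path) -> pd.DataFrame:
    """Read and validate a response-table CSV.

    Raises :class:`ResponseTableError` naming the offending 1-based file line
    for rows whose chosen label is not among the listed alternatives or whose
    response time is not positive.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "image_id": str,
                                  "machine_label": str, "chosen_label": str,
                                  "condition": str, "alternatives": str})
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseTableError(f"{path}: missing columns {missing}")
    df["condition"] = df["condition"].fillna("")
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        alts = str(row.alternatives).split(ALTERNATIVES_SEP)
        if str(row.chosen_label) not in alts:
            raise ResponseTableError(
                f"{path}:{line}: chosen_label {row.chosen_label!r} not among "
                f"alternatives {alts}"
            )
        if str(row.machine_label) not in alts:
            raise ResponseTableError(
                f"{path}:{line}: machine_label {row.machine_label!r} not among "
                f"alternatives {alts}"
            )
        if not row.rt_ms > 0:
            raise ResponseTableError(f"{path}:{line}: rt_ms must be positive")
    return df[RESPONSE_COLUMNS]


def write_response_table(table: pd.DataFrame, path) -> None:
    """Write a response table as CSV (lossless round-trip with the reader)."""
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ResponseTableError(f"cannot write table missing columns {missing}")
    table[RESPONSE_COLUMNS].to_csv(path, index=False)


#: Default mapping from deposited-data column names to the package schema.
#: The deposit's exact headers are configuration, not contract: pass an
#: explicit ``column_map`` when they differ.
DEFAULT_OSF_COLUMN_MAP = {
    "subject": "participant_id",
    "trial": "trial_index",
    "image": "image_id",
    "condition": "condition",
    "options": "alternatives",
    "dcnn_label": "machine_label",
    "response": "chosen_label",
    "rt": "rt_ms",
}


def import_osf_layout(path, column_map: dict | None = None) -> pd.DataFrame:
    """Import a deposited-data CSV layout into the package's response schema.

    ``column_map`` maps source column names to :data:`RESPONSE_COLUMNS` names;
    unmapped source columns are preserved and returned in the table's
    ``attrs["extra_columns"]``. Missing required columns raise an error listing
    what was expected.
    """
    column_map = DEFAULT_OSF_COLUMN_MAP if column_map is None else column_map
    df = pd.read_csv(path)
    present = {src: dst for src, dst in column_map.items() if src in df.columns}
    mapped = df.rename(columns=present)
    missing = [c for c in RESPONSE_COLUMNS if c not in mapped.columns]
    if missing:
        raise ResponseTableError(
            f"{path}: cannot map to response schema; missing {missing}. "
            f"Expected source columns like {sorted(column_map)} (pass column_map to override)."
        )
    extra = [c for c in mapped.columns if c not in RESPONSE_COLUMNS]
    out = mapped[RESPONSE_COLUMNS].copy()
    out.attrs["extra_columns"] = mapped[extra].to_dict(orient="list") if extra else {}
    return out


def write_manifest(out_dir, config: dict, seed: int) -> Path:
    """Write a reproducibility manifest (config hash, seed, package version)."""
    from advagree import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "advagree_version": __version__,
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
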