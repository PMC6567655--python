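"""Session state: every parameter and derived table needed to re-render
an analysis deterministically, plus a portable single-file archive.

The archive is a zip with a ``manifest.json`` (tool version, timestamp,
parameters, input digests, and a SHA-256 digest per table) and one TSV
per derived table.  Digests are verified on load, so silent corruption or
a missing table is detected.  The zip+manifest layout was chosen over a
language-native binary for cross-language portability.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .io import read_table, table_to_tsv


class CorruptArchiveError(RuntimeError):
    """Archive digests do not match its tables, or tables are missing."""


@dataclass
class SessionState:
    """Complete record of one analysis run."""

    params: dict
    input_digests: dict[str, str]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def table_tsv(self, name: str) -> str:
        return table_to_tsv(self.tables[name])


def file_digest(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _tsv_digest(tsv: str) -> str:
    return "sha256:" + hashlib.sha256(tsv.encode("utf-8")).hexdigest()


def save_state(state: SessionState, path: str | Path) -> None:
    """Write the session as a zip archive (manifest.json + one TSV per table)."""
    tsvs = {name: state.table_tsv(name) for name in state.tables}
    manifest = {
        "format": "pcascope-session",
        "version": state.version,
        "timestamp": state.timestamp,
        "params": state.params,
        "input_digests": state.input_digests,
        "tables": {name: _tsv_digest(t) for name, t in tsvs.items()},
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        for name, tsv in tsvs.items():
            zf.writestr(f"tables/{name}.tsv", tsv)


def load_state(path: str | Path) -> SessionState:
    """Read an archive back, verifying every table digest.

    A digest mismatch or missing table raises :class:`CorruptArchiveError`;
    an archive from a newer major version loads with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        major = str(manifest.get("version", "0")).split(".")[0]
        if major.isdigit() and int(major) > int(__version__.split(".")[0]):
            logger.warning(
                "archive written by newer major version %s (this is %s)",
                manifest["version"], __version__,
            )
        tables: dict[str, pd.DataFrame] = {}
        names = set(zf.namelist())
        for name, digest in manifest["tables"].items():
            member = f"tables/{name}.tsv"
            if member not in names:
                raise CorruptArchiveError(f"archive is missing table {name!r}")
            raw = zf.read(member)
            if _tsv_digest(raw.decode("utf-8")) != digest:
                raise CorruptArchiveError(f"digest mismatch for table {name!r}")
            import io as _stdio

            tables[name] = read_table(_stdio.StringIO(raw.decode("utf-8")))
    return SessionState(
        params=manifest["params"],
        input_digests=manifest["input_digests"],
        tables=tables,
        version=manifest["version"],
        timestamp=manifest["timestamp"],
    )
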