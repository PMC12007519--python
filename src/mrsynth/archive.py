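"""Deterministic NPZ archive helpers.

``np.savez`` stamps zip members with the current time, so two runs with the
same seed produce different bytes.  The writer here emits a standard NPZ
(readable by ``np.load``) with fixed member timestamps and sorted keys, so
identical content always yields identical files.
"""

from __future__ import annotations

import io
import zipfile

import numpy as np

_EPOCH = (1980, 1, 1, 0, 0, 0)


class ArchiveError(ValueError):
    """Raised when an archive is missing a required key or is malformed."""


def savez_deterministic(path, **arrays) -> None:
    """Write ``arrays`` to ``path`` as an NPZ with reproducible bytes."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for key in sorted(arrays):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[key]))
            info = zipfile.ZipInfo(f"{key}.npy", date_time=_EPOCH)
            zf.writestr(info, buf.getvalue())


def load_npz(path) -> dict[str, np.ndarray]:
    with np.load(path, allow_pickle=False) as npz:
        return {k: npz[k] for k in npz.files}


def require_keys(data: dict, keys, context: str = "archive") -> None:
    for key in keys:
        if key not in data:
            raise ArchiveError(f"{context} is missing required key {key!r}")
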