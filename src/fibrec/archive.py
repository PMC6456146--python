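"""Named-array archive: a zip of .npy members plus a JSON metadata member.

Complex arrays are stored natively in npy format.  Member timestamps are
fixed so that writing the same content twice produces identical bytes,
which makes archives safely diffable and cacheable.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path

import numpy as np

_EPOCH = (1980, 1, 1, 0, 0, 0)
META_MEMBER = "meta.json"


def save_archive(path, arrays: dict, meta: dict | None = None) -> None:
    """Write named arrays and JSON metadata to a deterministic zip archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=_EPOCH)
            zf.writestr(info, buf.getvalue())
        info = zipfile.ZipInfo(META_MEMBER, date_time=_EPOCH)
        zf.writestr(info, json.dumps(meta or {}, indent=2, sort_keys=True))


def load_archive(path) -> tuple[dict, dict]:
    """Read back ``(arrays, meta)`` from an archive written by save_archive."""
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {}
    with zipfile.ZipFile(path, "r") as zf:
        for name in zf.namelist():
            if name == META_MEMBER:
                meta = json.loads(zf.read(name).decode())
            elif name.endswith(".npy"):
                arrays[name[:-4]] = np.lib.format.read_array(io.BytesIO(zf.read(name)))
    return arrays, meta


def export_view(path_prefix, complex_image: np.ndarray) -> list[Path]:
    """8-bit PNG exports of a complex image for inspection only.

    Writes ``<prefix>_amplitude.png`` (linear scaling of the modulus to
    0..255) and ``<prefix>_phase.png`` (wrapped phase mapped from
    (-pi, pi] to 0..255).  Not a data format: scaling is lossy.
    """
    import imageio.v3 as iio

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    amp = np.abs(complex_image)
    lo, hi = amp.min(), amp.max()
    amp8 = np.zeros_like(amp, dtype=np.uint8) if hi == lo else (
        (amp - lo) / (hi - lo) * 255
    ).astype(np.uint8)
    phase = np.angle(complex_image)
    ph8 = ((phase + np.pi) / (2 * np.pi) * 255).astype(np.uint8)
    out_a = prefix.with_name(prefix.name + "_amplitude.png")
    out_p = prefix.with_name(prefix.name + "_phase.png")
    iio.imwrite(out_a, amp8)
    iio.imwrite(out_p, ph8)
    return [out_a, out_p]
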