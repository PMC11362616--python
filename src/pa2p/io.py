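"""TIFF stack I/O with axis metadata.

Stacks are stored as multi-page 16-bit unsigned TIFF, one page per frame (time
series) or per z plane (volumes), axis order (frame/z, y, x).  The axis
semantics travel in the image description as JSON so a round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FormatError", "save_stack", "load_stack"]


class FormatError(RuntimeError):
    """A stack file could not be read; names the offending page if known."""


def save_stack(stack: np.ndarray, path: str | Path, axes: str = "TYX") -> None:
    """Write a (n, ny, nx) stack as multi-page uint16 TIFF.

    ``axes`` documents the leading axis: "TYX" for frame series, "ZYX" for
    volumes.  Values are clipped to the uint16 range.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (frame/z, y, x)")
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    meta = json.dumps({"axes": axes, "n_pages": int(data.shape[0])})
    tifffile.imwrite(
        Path(path), data, description=meta, metadata=None, photometric="minisblack"
    )


def load_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF stack and its axis metadata.

    Returns (stack, metadata); metadata holds at least ``axes``.  Malformed
    or truncated files raise :class:`FormatError` naming the failing page.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = []
            for i, page in enumerate(tif.pages):
                try:
                    pages.append(page.asarray())
                except Exception as err:
                    raise FormatError(f"cannot read page {i} of {path}: {err}") from err
            if not pages:
                raise FormatError(f"{path} contains no image pages")
            desc = tif.pages[0].description or "{}"
    except FormatError:
        raise
    except Exception as err:
        raise FormatError(f"cannot open {path}: {err}") from err
    try:
        meta = json.loads(desc)
        if not isinstance(meta, dict):
            meta = {}
    except json.JSONDecodeError:
        meta = {}
    meta.setdefault("axes", "TYX")
    expected = meta.get("n_pages")
    if expected is not None and len(pages) != expected:
        raise FormatError(
            f"{path} is truncated: page {len(pages)} of {expected} missing"
        )
    return np.stack(pages), meta
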