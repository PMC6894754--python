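"""Small shared IO helpers."""
from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import IO


def deterministic_gzip_writer(path: str | Path, level: int = 6) -> IO[str]:
    """Open a gzip text writer whose output bytes do not depend on wall time.

    Plain ``gzip.open`` embeds the current mtime in the member header, which
    breaks byte-identical re-runs; this pins mtime to 0 and omits the name.
    """
    raw = open(path, "wb")
    gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, compresslevel=level, mtime=0)
    return io.TextIOWrapper(gz, encoding="utf-8", newline="")


def open_text_auto(path: str | Path) -> IO[str]:
    """Open text for reading, transparently decompressing ``.gz``."""
    if _is_gzipped(path):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_gzipped(path: str | Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"
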