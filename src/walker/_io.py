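"""gzip-transparent text file opening."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)
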