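"""Locating reference structures by PDB identifier.

The case study of this package is the third PDZ domain of PSD-95 with its
bound peptide ligand, PDB entry 1BE9.  Deposited coordinates are not
redistributed here; :func:`resolve_structure` looks for ``<id>.pdb`` in local
data directories and otherwise tries to download the entry from the RCSB.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request
from pathlib import Path
from typing import Iterable, Optional

from .errors import DatasetUnavailableError

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"

_DEFAULT_DIRS = ("data", ".")


def resolve_structure(
    pdb_id: str,
    data_dirs: Iterable[os.PathLike | str] = _DEFAULT_DIRS,
    download: bool = True,
    cache_dir: Optional[os.PathLike | str] = None,
    timeout: float = 15.0,
) -> str:
    """Return PDB-format text for ``pdb_id``.

    Searches ``<dir>/<id>.pdb`` (lower- and upper-case) in ``data_dirs``, the
    repository ``data/`` directory next to an installed source tree, then
    attempts an RCSB download (cached to ``cache_dir`` when given).
    """
    pdb_id = pdb_id.lower()
    candidates = []
    for d in data_dirs:
        candidates.append(Path(d) / f"{pdb_id}.pdb")
        candidates.append(Path(d) / f"{pdb_id.upper()}.pdb")
    # data/ directory at the repository root of an editable install
    repo_data = Path(__file__).resolve().parents[2] / "data"
    candidates.append(repo_data / f"{pdb_id}.pdb")
    for path in candidates:
        if path.is_file():
            return path.read_text()

    if download:
        url = RCSB_URL.format(pdb_id=pdb_id.upper())
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                text = resp.read().decode("utf-8", errors="replace")
            if cache_dir is not None:
                cache = Path(cache_dir)
                cache.mkdir(parents=True, exist_ok=True)
                (cache / f"{pdb_id}.pdb").write_text(text)
            return text
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            raise DatasetUnavailableError(
                f"PDB entry {pdb_id} not found locally and download failed "
                f"({exc}). Place the file at data/{pdb_id}.pdb "
                f"(e.g. curl -o data/{pdb_id}.pdb {url})."
            ) from exc
    raise DatasetUnavailableError(
        f"PDB entry {pdb_id} not found in {list(map(str, candidates))}"
    )
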