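"""Optional download of deposited coordinates (reproduction runs only).

Everything else in the package works offline; this module exists so the
printed numbers can be recomputed on the deposited models (9I2B and the
comparators) when a network is available.  Downloads are cached, verified
to parse, and never silently partial.
"""

from __future__ import annotations

import re
import urllib.error
import urllib.request
from pathlib import Path

from .errors import FetchError

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"
_DEFAULT_CACHE = Path.home() / ".cache" / "arpgeom"


def fetch_structure(accession: str, destination: str | Path | None = None,
                    retries: int = 2, timeout: float = 30.0) -> Path:
    """Download (or reuse a cached) mmCIF for a PDB accession.

    Returns the path of a non-empty, parseable mmCIF.  A warm cache makes
    no network use.  Raises :class:`FetchError` on malformed ids, network
    failure (after ``retries`` attempts) or unparseable content.
    """
    pdb_id = accession.strip().upper()
    if not re.fullmatch(r"[0-9][A-Z0-9]{3}", pdb_id):
        raise FetchError(f"malformed PDB id {accession!r}")
    cache = Path(destination) if destination else _DEFAULT_CACHE
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{pdb_id.lower()}.cif"
    if target.exists() and target.stat().st_size > 0:
        return target

    url = _RCSB_URL.format(pdb_id=pdb_id)
    last_error: Exception | None = None
    for attempt in range(retries + 1):
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
            if not data:
                raise FetchError(f"{url} returned empty content")
            tmp = target.with_suffix(".part")
            tmp.write_bytes(data)
            _verify_parseable(tmp)
            tmp.rename(target)
            return target
        except (urllib.error.URLError, OSError, FetchError) as exc:
            last_error = exc
    raise FetchError(
        f"could not fetch {pdb_id} after {retries + 1} attempt(s): "
        f"{last_error}")


def _verify_parseable(path: Path) -> None:
    from .structure_io import read_structure
    model = read_structure(path, fmt="mmcif")
    if model.n_atoms() == 0:
        raise FetchError(f"{path} parsed to zero atoms")
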