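"""Plain-text readers/writers: samples, dictionary configs, results.

Samples are one numeric value per row (optional single header line);
dictionaries and run configurations travel as YAML or JSON; fit results as
JSON (full precision) or CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .dictionary import Dictionary
from .solver import FitResult

__all__ = ["read_samples", "write_samples", "read_dictionary",
           "write_dictionary", "write_fit_result", "read_fit_result"]


class ParseError(ValueError):
    pass


def read_samples(path) -> tuple[np.ndarray, bool]:
    """Read one-value-per-row samples.

    Returns ``(values, is_integer)`` where the flag marks integer-only
    content (eligible for discrete dictionaries).  A single non-numeric
    first row is treated as a header; any later non-numeric row is a parse
    error naming its line number, as are NaN/infinite values.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            try:
                val = float(text)
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header
                raise ParseError(
                    f"{path}: non-numeric value {text!r} at line {lineno}")
            if not np.isfinite(val):
                raise ParseError(f"{path}: non-finite value at line {lineno}")
            values.append(val)
    if not values:
        raise ParseError(f"{path}: no numeric rows found")
    arr = np.asarray(values, dtype=float)
    return arr, bool(np.all(arr == np.floor(arr)))


def write_samples(path, values) -> None:
    np.savetxt(path, np.asarray(values, dtype=float).reshape(-1, 1),
               fmt="%.17g")


def read_dictionary(path) -> Dictionary:
    """Load a dictionary config (YAML or JSON; extension decides).

    Expected keys: ``family``; for Gaussians ``means`` and ``sigmas`` (or a
    ``components`` list of param dicts), for Poisson ``rates``; optional
    ``normalize: true``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dictionary file not found: {path}")
    with path.open() as fh:
        cfg = (json.load(fh) if path.suffix.lower() == ".json"
               else yaml.safe_load(fh))
    if "components" in cfg:
        d = Dictionary.from_config(cfg)
    elif cfg["family"] == "gaussian":
        d = Dictionary.gaussian(cfg["means"], cfg["sigmas"])
    elif cfg["family"] == "poisson":
        d = Dictionary.poisson(cfg["rates"])
    else:
        raise ParseError(f"{path}: cannot build a {cfg['family']!r} "
                         "dictionary from shorthand keys")
    if cfg.get("normalize"):
        d = d.normalize()
    return d


def write_dictionary(path, dictionary: Dictionary) -> None:
    path = Path(path)
    cfg = dictionary.to_config()
    with path.open("w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(cfg, fh, indent=1)
        else:
            yaml.safe_dump(cfg, fh)


def write_fit_result(path, result: FitResult, extra: dict | None = None) -> None:
    """JSON dump of a fit result at full float precision."""
    payload = result.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_result(path) -> dict:
    return json.loads(Path(path).read_text())
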