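"""Readers/writers for Praat text formats and model serialization.

PitchTier files carry the restyled f0 point series and TextGrid files the
segment boundaries, so an external PSOLA resynthesizer (e.g. Praat itself)
can consume the package's restyling specifications.  Both the full
("ooTextFile") and the short PitchTier dialects are supported.  Praat
stores times in seconds; :class:`~soprosody.contours.Contour` uses
milliseconds, converted at the boundary.  Values are written as-is
(semitones in this pipeline, where Praat would usually hold Hz).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .contours import Contour, FPCAModel

__all__ = [
    "write_pitch_tier",
    "read_pitch_tier",
    "write_textgrid",
    "read_textgrid",
    "contour_to_csv",
    "contour_from_csv",
    "model_to_json",
    "model_from_json",
]

_MS = 1e-3  # Praat times are in seconds


def write_pitch_tier(contour: Contour, path: str | Path, dialect: str = "full") -> None:
    """Write a contour as a Praat PitchTier text file (``full`` or ``short``)."""
    t_s = contour.times * _MS
    xmin, xmax = t_s[0], t_s[-1]
    lines = ['File type = "ooTextFile"', 'Object class = "PitchTier"', ""]
    if dialect == "full":
        lines += [f"xmin = {float(xmin)!r}", f"xmax = {float(xmax)!r}",
                  f"points: size = {t_s.size}"]
        for i, (t, v) in enumerate(zip(t_s, contour.values), start=1):
            lines += [f"points [{i}]:", f"    number = {float(t)!r}",
                      f"    value = {float(v)!r}"]
    elif dialect == "short":
        lines += [repr(float(xmin)), repr(float(xmax)), str(t_s.size)]
        for t, v in zip(t_s, contour.values):
            lines += [repr(float(t)), repr(float(v))]
    else:
        raise ValueError("dialect must be 'full' or 'short'")
    Path(path).write_text("\n".join(lines) + "\n")


_NUM = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")


def read_pitch_tier(path: str | Path, label: str = "") -> Contour:
    """Read a PitchTier text file (either dialect) into a Contour (times in ms)."""
    text = Path(path).read_text()
    if "PitchTier" not in text:
        raise ValueError(f"{path} is not a PitchTier file")
    body = text.split("\n", 2)[2] if text.count("\n") >= 2 else ""
    numbers = [float(m.group()) for line in body.splitlines()
               for m in _NUM.finditer(_strip_praat_line(line))]
    # numbers: xmin, xmax, size, then (time, value) pairs
    if len(numbers) < 3:
        raise ValueError(f"{path}: truncated PitchTier")
    size = int(numbers[2])
    pairs = numbers[3:3 + 2 * size]
    if len(pairs) != 2 * size:
        raise ValueError(f"{path}: expected {size} points")
    times = np.asarray(pairs[0::2]) / _MS
    values = np.asarray(pairs[1::2])
    return Contour(times=times, values=values, label=label)


def _strip_praat_line(line: str) -> str:
    # drop index brackets like "points [3]:" so only data numbers remain
    line = re.sub(r"\[\d+\]", "", line)
    return line


def write_textgrid(
    tiers: dict[str, Sequence[tuple[float, float, str]]], path: str | Path
) -> None:
    """Write interval tiers to a Praat TextGrid text file.

    ``tiers`` maps tier name to a list of (xmin_ms, xmax_ms, text) intervals.
    """
    if not tiers:
        raise ValueError("at least one tier required")
    all_iv = [iv for ivs in tiers.values() for iv in ivs]
    xmin = min(iv[0] for iv in all_iv) * _MS
    xmax = max(iv[1] for iv in all_iv) * _MS
    out = ['File type = "ooTextFile"', 'Object class = "TextGrid"', "",
           f"xmin = {float(xmin)!r}", f"xmax = {float(xmax)!r}", "tiers? <exists>",
           f"size = {len(tiers)}", "item []:"]
    for k, (name, ivs) in enumerate(tiers.items(), start=1):
        out += [f"    item [{k}]:", '        class = "IntervalTier"',
                f'        name = "{name}"',
                f"        xmin = {float(min(iv[0] for iv in ivs) * _MS)!r}",
                f"        xmax = {float(max(iv[1] for iv in ivs) * _MS)!r}",
                f"        intervals: size = {len(ivs)}"]
        for j, (lo, hi, txt) in enumerate(ivs, start=1):
            out += [f"        intervals [{j}]:",
                    f"            xmin = {float(lo * _MS)!r}",
                    f"            xmax = {float(hi * _MS)!r}",
                    f'            text = "{txt}"']
    Path(path).write_text("\n".join(out) + "\n")


def read_textgrid(path: str | Path) -> dict[str, list[tuple[float, float, str]]]:
    """Read interval tiers from a full-dialect TextGrid (times back in ms)."""
    text = Path(path).read_text()
    if "TextGrid" not in text:
        raise ValueError(f"{path} is not a TextGrid file")
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    current: list[tuple[float, float, str]] | None = None
    lo = hi = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("name ="):
            name = line.split("=", 1)[1].strip().strip('"')
            current = tiers.setdefault(name, [])
            lo = hi = None
        elif line.startswith("xmin =") and current is not None:
            lo = float(line.split("=")[1])
        elif line.startswith("xmax =") and current is not None:
            hi = float(line.split("=")[1])
        elif line.startswith("text =") and current is not None:
            txt = line.split("=", 1)[1].strip().strip('"')
            if lo is not None and hi is not None:
                current.append((lo / _MS, hi / _MS, txt))
    # the tier header's own xmin/xmax precede the first interval and are
    # overwritten before any 'text =' line, so only true intervals are kept
    return tiers


def contour_to_csv(contour: Contour, path: str | Path) -> None:
    """CSV fallback: two columns time_ms, f0_st."""
    with open(path, "w") as fh:
        fh.write("time_ms,f0_st\n")
        for t, v in zip(contour.times, contour.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def contour_from_csv(path: str | Path, label: str = "") -> Contour:
    data = np.genfromtxt(path, delimiter=",", names=True)
    return Contour(times=np.atleast_1d(data["time_ms"]),
                   values=np.atleast_1d(data["f0_st"]), label=label)


def model_to_json(model: FPCAModel, path: str | Path | None = None) -> str:
    """Serialize an FPCA model (grid, mean, components, score SDs) to JSON."""
    doc = json.dumps(
        {
            "grid": model.grid.tolist(),
            "mean_curve": model.mean_curve.tolist(),
            "components": model.components.tolist(),
            "score_sds": model.score_sds.tolist(),
        },
        indent=1,
    )
    if path is not None:
        Path(path).write_text(doc)
    return doc


def model_from_json(source: str | Path) -> FPCAModel:
    """Load a model from a JSON string or file path."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    doc = json.loads(text)
    return FPCAModel(
        grid=np.asarray(doc["grid"]),
        mean_curve=np.asarray(doc["mean_curve"]),
        components=np.asarray(doc["components"]),
        score_sds=np.asarray(doc["score_sds"]),
    )
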