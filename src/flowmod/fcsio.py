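"""Minimal FCS 3.0/3.1 reading and writing for assay event tables.

Covers the slice of the FCS standard this pipeline needs: list-mode data,
float (``$DATATYPE F``) written as FCS 3.1 / float32, plus reading of
integer (``$DATATYPE I``) 3.0-style files with linear scaling.  Channels
are matched by ``$PnN`` (short name) with ``$PnS`` as fallback; extra
channels are ignored with a log entry, and a file lacking FSC-H still
loads (the doublet gate is skipped downstream).

Also the plate-layout and sample-metadata CSV round-trip lives here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CHANNELS, EventTable

logger = logging.getLogger(__name__)

_HEADER_LEN = 58
_DELIM = b"/"


class FCSFormatError(ValueError):
    """File does not conform to the supported FCS subset."""


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def write_fcs(table: EventTable, path: str | Path) -> None:
    """Write an event table as FCS 3.1, list mode, little-endian float32."""
    channels = [c for c in CHANNELS if c in table.events.columns]
    data = np.ascontiguousarray(
        table.events[channels].to_numpy(dtype="<f4")
    )
    n_events, n_par = data.shape
    n_bytes = data.nbytes

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # fixed-width placeholders: patched below once TEXT length is known
        "$BEGINDATA": "%012d" % 0,
        "$ENDDATA": "%012d" % 0,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(channels, start=1):
        col = table.events[name]
        kw[f"$P{i}N"] = name
        kw[f"$P{i}S"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(float(col.max()))) + 1)

    def render(kws: dict[str, str]) -> bytes:
        d = _DELIM
        out = d
        for k, v in kws.items():
            out += k.encode("ascii") + d + v.encode("ascii") + d
        return out

    text = render(kw)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + n_bytes - 1
    kw["$BEGINDATA"] = "%012d" % data_start
    kw["$ENDDATA"] = "%012d" % data_end
    text = render(kw)
    assert text_end == text_start + len(text) - 1  # widths fixed by padding

    header = b"FCS3.1    " + "".join(
        "%8d" % v for v in (text_start, text_end, data_start, data_end, 0, 0)
    ).encode("ascii")
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------


def _parse_text(raw: bytes, offset: int) -> dict[str, str]:
    if not raw:
        raise FCSFormatError(f"empty TEXT segment at byte {offset}")
    delim = raw[:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FCSFormatError(
            f"corrupt TEXT segment near byte {offset}: odd keyword/value count"
        )
    kw = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("ascii", errors="replace").strip().upper()
        kw[key] = parts[i + 1].decode("ascii", errors="replace").strip()
    return kw


def read_fcs(path: str | Path) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Requires FSC-A, SSC-A, APC-A and PE-A; FSC-H is optional (its absence
    is logged and the doublet gate is skipped later).
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FCSFormatError(f"{path}: file too short for an FCS header")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        offsets = [int(raw[10 + 8 * i : 18 + 8 * i]) for i in range(4)]
    except ValueError as exc:
        raise FCSFormatError(f"{path}: malformed header offsets") from exc
    text_start, text_end, data_start, data_end = offsets
    kw = _parse_text(raw[text_start : text_end + 1], text_start)

    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    try:
        n_events = int(kw["$TOT"])
        n_par = int(kw["$PAR"])
        datatype = kw["$DATATYPE"]
        byteord = kw["$BYTEORD"]
    except KeyError as exc:
        raise FCSFormatError(f"{path}: missing required keyword {exc}") from exc
    if n_events == 0:
        raise FCSFormatError(f"{path}: file contains zero events")
    if kw.get("$MODE", "L") != "L":
        raise FCSFormatError(f"{path}: only list-mode ($MODE L) is supported")

    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}")
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

    endian = "<" if byteord.startswith("1") else ">"
    buf = raw[data_start : data_end + 1]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FCSFormatError(f"{path}: float data requires $PnB 32")
        arr = np.frombuffer(buf, dtype=f"{endian}f4")
    elif datatype == "D":
        arr = np.frombuffer(buf, dtype=f"{endian}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FCSFormatError(
                f"{path}: integer data supported only for uniform 16/32-bit widths"
            )
        arr = np.frombuffer(buf, dtype=f"{endian}u{bits[0] // 8}")
    else:
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")
    if arr.size < n_events * n_par:
        raise FCSFormatError(
            f"{path}: data segment truncated at byte {data_start + arr.nbytes}"
        )
    mat = arr[: n_events * n_par].astype(float).reshape(n_events, n_par)

    frame = pd.DataFrame(mat, columns=names)
    extra = [c for c in names if c not in CHANNELS]
    if extra:
        logger.info("%s: ignoring extra channels %s", path, extra)
        frame = frame.drop(columns=extra)
    required = [c for c in CHANNELS if c != "FSC-H"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FCSFormatError(f"{path}: missing required channel(s) {missing}")
    if "FSC-H" not in frame.columns:
        logger.warning("%s: FSC-H absent; doublet exclusion will be skipped", path)
    return EventTable(events=frame.reset_index(drop=True), meta={"path": str(path)})


# ---------------------------------------------------------------------------
# Plate layout / metadata CSVs
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = ["plate", "well", "sample_id", "role", "reciprocal_dilution"]
METADATA_COLUMNS = ["sample_id", "category", "true_conc_pM", "ria_pM", "blinded_truth"]


def write_layout(layout: pd.DataFrame, path: str | Path) -> None:
    layout[LAYOUT_COLUMNS].to_csv(path, index=False)


def read_layout(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"plate": str, "well": str, "sample_id": str})
    missing = [c for c in LAYOUT_COLUMNS if c not in frame.columns]
    if missing:
        raise FCSFormatError(f"{path}: layout CSV missing columns {missing}")
    if len(frame) == 0:
        raise FCSFormatError(f"{path}: plate layout is empty")
    return frame


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in metadata.columns]
    metadata[cols].to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"sample_id": str, "category": str})
    if "sample_id" not in frame.columns or "category" not in frame.columns:
        raise FCSFormatError(f"{path}: metadata CSV needs sample_id and category")
    if "blinded_truth" in frame.columns:
        frame["blinded_truth"] = frame["blinded_truth"].where(
            frame["blinded_truth"].notna(), None
        )
    return frame
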