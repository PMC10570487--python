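"""Minimal reader/writer for XDF (eXtensible Data Format) multi-stream files.

Covers the subset produced by LabStreamingLayer recorders and used by this
package: file header, stream header/footer XML, numeric and string sample
chunks, clock-offset chunks and boundary chunks.  Numeric formats float32,
double64, int8/16/32/64 are supported; irregular-rate streams (markers, gaze)
must carry explicit per-sample timestamps, which LSL recorders emit.

Not a general-purpose implementation: no de-jittering of timestamps and no
piecewise clock-offset regression — offsets are applied as their mean, which
is adequate for recordings made on a single host clock.
"""

from __future__ import annotations

import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

MAGIC = b"XDF:"

_FMT_DTYPES = {
    "float32": np.dtype("<f4"),
    "double64": np.dtype("<f8"),
    "int8": np.dtype("<i1"),
    "int16": np.dtype("<i2"),
    "int32": np.dtype("<i4"),
    "int64": np.dtype("<i8"),
}


class XDFError(ValueError):
    """Malformed or unsupported XDF content."""


@dataclass
class XDFStream:
    stream_id: int
    name: str
    type: str
    channel_count: int
    nominal_srate: float
    channel_format: str
    timestamps: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: (n_samples, channel_count) array for numeric streams, list[list[str]] otherwise
    data: object = None
    clock_offset: float = 0.0


def _read_varlen(buf: bytes, pos: int) -> tuple[int, int]:
    nbytes = buf[pos]
    pos += 1
    if nbytes == 1:
        return buf[pos], pos + 1
    if nbytes == 4:
        return struct.unpack_from("<I", buf, pos)[0], pos + 4
    if nbytes == 8:
        return struct.unpack_from("<Q", buf, pos)[0], pos + 8
    raise XDFError(f"invalid varlen size {nbytes}")


def _varlen(n: int) -> bytes:
    if n < 256:
        return bytes([1, n])
    if n < 2**32:
        return bytes([4]) + struct.pack("<I", n)
    return bytes([8]) + struct.pack("<Q", n)


def _parse_header_xml(xml: str) -> dict:
    root = ET.fromstring(xml)

    def get(tag: str, default: str = "") -> str:
        el = root.find(tag)
        return el.text if el is not None and el.text else default

    return {
        "name": get("name"),
        "type": get("type"),
        "channel_count": int(get("channel_count", "1")),
        "nominal_srate": float(get("nominal_srate", "0")),
        "channel_format": get("channel_format", "float32"),
    }


def load_xdf(path) -> list[XDFStream]:
    """Parse an XDF file into a list of streams with aligned timestamps."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if buf[:4] != MAGIC:
        raise XDFError(f"{path}: not an XDF file (bad magic)")
    pos = 4
    streams: dict[int, XDFStream] = {}
    chunks: dict[int, list] = {}
    offsets: dict[int, list[float]] = {}
    while pos < len(buf):
        length, pos = _read_varlen(buf, pos)
        if pos + length > len(buf):
            raise XDFError(f"{path}: truncated chunk at byte {pos}")
        tag = struct.unpack_from("<H", buf, pos)[0]
        content = buf[pos + 2 : pos + length]
        pos += length
        if tag == 2:  # stream header
            sid = struct.unpack_from("<I", content, 0)[0]
            info = _parse_header_xml(content[4:].decode("utf-8"))
            streams[sid] = XDFStream(stream_id=sid, **info)
            chunks[sid] = []
            offsets[sid] = []
        elif tag == 3:  # samples
            sid = struct.unpack_from("<I", content, 0)[0]
            if sid not in streams:
                raise XDFError(f"{path}: samples for undeclared stream {sid}")
            chunks[sid].append(content[4:])
        elif tag == 4:  # clock offset
            sid = struct.unpack_from("<I", content, 0)[0]
            _, off = struct.unpack_from("<dd", content, 4)
            offsets.setdefault(sid, []).append(off)
        elif tag in (1, 5, 6):  # file header / boundary / stream footer
            continue
        else:
            raise XDFError(f"{path}: unknown chunk tag {tag}")

    for sid, st in streams.items():
        ts_list: list[float] = []
        is_string = st.channel_format == "string"
        rows: list = []
        last_ts = 0.0
        for raw in chunks[sid]:
            n, p = _read_varlen(raw, 0)
            for _ in range(n):
                tsbytes = raw[p]
                p += 1
                if tsbytes == 8:
                    last_ts = struct.unpack_from("<d", raw, p)[0]
                    p += 8
                elif tsbytes == 0:
                    last_ts = last_ts + (1.0 / st.nominal_srate if st.nominal_srate else 0.0)
                else:
                    raise XDFError("invalid timestamp-bytes flag")
                ts_list.append(last_ts)
                if is_string:
                    vals = []
                    for _c in range(st.channel_count):
                        slen, p = _read_varlen(raw, p)
                        vals.append(raw[p : p + slen].decode("utf-8"))
                        p += slen
                    rows.append(vals)
                else:
                    dt = _FMT_DTYPES[st.channel_format]
                    nb = dt.itemsize * st.channel_count
                    rows.append(np.frombuffer(raw, dtype=dt, count=st.channel_count, offset=p))
                    p += nb
        off = float(np.mean(offsets[sid])) if offsets.get(sid) else 0.0
        st.clock_offset = off
        st.timestamps = np.asarray(ts_list, dtype=float) + off
        if is_string:
            st.data = rows
        else:
            st.data = (
                np.vstack(rows).astype(float)
                if rows
                else np.empty((0, st.channel_count))
            )
    return list(streams.values())


def _header_xml(st: XDFStream) -> bytes:
    srate = f"{st.nominal_srate:.6f}".rstrip("0").rstrip(".")
    return (
        "<?xml version=\"1.0\"?><info>"
        f"<name>{st.name}</name><type>{st.type}</type>"
        f"<channel_count>{st.channel_count}</channel_count>"
        f"<nominal_srate>{srate}</nominal_srate>"
        f"<channel_format>{st.channel_format}</channel_format>"
        "</info>"
    ).encode("utf-8")


def _chunk(tag: int, content: bytes) -> bytes:
    return _varlen(len(content) + 2) + struct.pack("<H", tag) + content


def save_xdf(path, streams: list[XDFStream]) -> None:
    """Write streams to an XDF file with explicit per-sample timestamps."""
    out = [MAGIC, _chunk(1, b"<?xml version=\"1.0\"?><info><version>1.0</version></info>")]
    for st in streams:
        out.append(_chunk(2, struct.pack("<I", st.stream_id) + _header_xml(st)))
    for st in streams:
        body = [_varlen(len(st.timestamps))]
        is_string = st.channel_format == "string"
        dt = None if is_string else _FMT_DTYPES[st.channel_format]
        for k, ts in enumerate(np.asarray(st.timestamps, dtype=float)):
            body.append(b"\x08" + struct.pack("<d", ts))
            if is_string:
                for v in st.data[k]:
                    enc = v.encode("utf-8")
                    body.append(_varlen(len(enc)) + enc)
            else:
                body.append(np.ascontiguousarray(st.data[k], dtype=dt).tobytes())
        out.append(_chunk(3, struct.pack("<I", st.stream_id) + b"".join(body)))
    for st in streams:
        out.append(_chunk(6, struct.pack("<I", st.stream_id) + _header_xml(st)))
    with open(path, "wb") as fh:
        fh.write(b"".join(out))
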