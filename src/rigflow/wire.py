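"""Self-describing binary framing for packet payloads.

Every message on a data link is a payload: an ordered list of items, one per
declared output of the emitting node.  An item is either an n-dimensional
numeric tensor or a string-keyed record.  The framing is self-describing so
a receiver needs no side channel to decode, and round-trips are bit-exact
for integer tensors.

Frame layout (all integers little-endian):

    payload  := MAGIC(2) n_items(u32) item*
    item     := kind(1) body_len(u64) body
    kind 'T' := tensor   body = dtype_len(u16) dtype_str ndim(u8) dims(u64*) raw C-order buffer
    kind 'R' := record   body = UTF-8 JSON object

Records are JSON-encoded: string keys with scalar / string / list / nested
record values, which covers the key-value messages nodes exchange (trial
definitions, results, command strings).  NaN/Inf floats are permitted.
"""

from __future__ import annotations

import json
import struct
from typing import Any, List, Union

import numpy as np

MAGIC = b"\xaf\x01"

PayloadItem = Union[np.ndarray, dict]


class WireError(ValueError):
    """Raised when a frame cannot be encoded or decoded."""


def _encode_tensor(arr: np.ndarray) -> bytes:
    if arr.dtype.kind not in "biufc":
        raise WireError(f"tensor dtype {arr.dtype!r} is not numeric")
    if arr.dtype.byteorder == ">":
        arr = arr.astype(arr.dtype.newbyteorder("<"))
    dtype_str = arr.dtype.str.encode("ascii")
    head = struct.pack("<H", len(dtype_str)) + dtype_str
    head += struct.pack("<B", arr.ndim)
    head += struct.pack(f"<{arr.ndim}Q", *arr.shape)
    return head + arr.tobytes(order="C")


def _decode_tensor(body: bytes) -> np.ndarray:
    try:
        (dlen,) = struct.unpack_from("<H", body, 0)
        off = 2
        dtype = np.dtype(body[off : off + dlen].decode("ascii"))
        off += dlen
        (ndim,) = struct.unpack_from("<B", body, off)
        off += 1
        shape = struct.unpack_from(f"<{ndim}Q", body, off)
        off += 8 * ndim
        arr = np.frombuffer(body[off:], dtype=dtype)
    except (struct.error, TypeError, UnicodeDecodeError) as exc:
        raise WireError(f"malformed tensor frame: {exc}") from exc
    expect = int(np.prod(shape, dtype=np.int64)) if ndim else 1
    if ndim == 0:
        if arr.size != 1:
            raise WireError("scalar tensor frame with wrong buffer size")
        return arr.reshape(())
    if arr.size != expect:
        raise WireError("tensor frame buffer does not match declared shape")
    return arr.reshape(shape)


def _check_record(obj: Any, path: str = "record") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            if not isinstance(k, str):
                raise WireError(f"{path}: record keys must be strings, got {k!r}")
            _check_record(v, f"{path}.{k}")
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            _check_record(v, f"{path}[{i}]")
    elif obj is not None and not isinstance(obj, (str, bool, int, float)):
        raise WireError(f"{path}: unsupported value type {type(obj).__name__}")


def encode_item(item: PayloadItem) -> bytes:
    if isinstance(item, np.ndarray):
        body = _encode_tensor(item)
        kind = b"T"
    elif isinstance(item, dict):
        _check_record(item)
        body = json.dumps(item, separators=(",", ":"), allow_nan=True).encode("utf-8")
        kind = b"R"
    else:
        raise WireError(
            f"payload items must be numeric tensors or records, got {type(item).__name__}"
        )
    return kind + struct.pack("<Q", len(body)) + body


def decode_item(buf: bytes, offset: int = 0) -> tuple[PayloadItem, int]:
    """Decode one item starting at ``offset``; return (item, next offset)."""
    if len(buf) < offset + 9:
        raise WireError("truncated item header")
    kind = buf[offset : offset + 1]
    (blen,) = struct.unpack_from("<Q", buf, offset + 1)
    start = offset + 9
    end = start + blen
    if end > len(buf):
        raise WireError("truncated item body")
    body = buf[start:end]
    if kind == b"T":
        return _decode_tensor(body), end
    if kind == b"R":
        try:
            obj = json.loads(body.decode("utf-8"))
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise WireError(f"malformed record frame: {exc}") from exc
        if not isinstance(obj, dict):
            raise WireError("record frame does not hold an object")
        return obj, end
    raise WireError(f"unknown item kind {kind!r}")


def encode_payload(items: List[PayloadItem]) -> bytes:
    out = [MAGIC, struct.pack("<I", len(items))]
    out.extend(encode_item(it) for it in items)
    return b"".join(out)


def decode_payload(buf: bytes) -> List[PayloadItem]:
    if buf[:2] != MAGIC:
        raise WireError("bad magic: not a rigflow payload frame")
    if len(buf) < 6:
        raise WireError("truncated payload header")
    (n,) = struct.unpack_from("<I", buf, 2)
    items: List[PayloadItem] = []
    off = 6
    for _ in range(n):
        item, off = decode_item(buf, off)
        items.append(item)
    if off != len(buf):
        raise WireError("trailing bytes after last payload item")
    return items


def encode_packet(
    source_node: str, packet_id: int, timestamp_ns: int, items: List[PayloadItem]
) -> bytes:
    """Full data-link frame: routing header followed by the payload."""
    head = json.dumps(
        {"node": source_node, "id": int(packet_id), "t": int(timestamp_ns)},
        separators=(",", ":"),
    ).encode("utf-8")
    return struct.pack("<I", len(head)) + head + encode_payload(items)


def decode_packet(buf: bytes) -> tuple[str, int, int, List[PayloadItem]]:
    try:
        (hlen,) = struct.unpack_from("<I", buf, 0)
        head = json.loads(buf[4 : 4 + hlen].decode("utf-8"))
        node, pid, ts = head["node"], head["id"], head["t"]
    except (struct.error, json.JSONDecodeError, KeyError, UnicodeDecodeError) as exc:
        raise WireError(f"malformed packet header: {exc}") from exc
    items = decode_payload(buf[4 + hlen :])
    return node, int(pid), int(ts), items
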