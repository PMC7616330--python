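"""Minimal MessagePack-wire-format codec for document trees.

Encodes exactly the JSON data model the serializer uses — ``None``, bools,
ints, floats, strings, lists and string-keyed maps — using the MessagePack
framing (https://msgpack.org/).  Deliberately small and deterministic:

* floats are always written as float64 (0xcb), never downcast;
* ints use the smallest encoding that holds the value;
* map key order is preserved (insertion order), never sorted here —
  canonical ordering is the serializer's job.

The decoder accepts the full fixstr/str, fixint/int, fixmap/map,
fixarray/array, nil, bool, float32/64 subset, which covers anything a
conforming encoder produces for this data model.
"""

from __future__ import annotations

import struct

__all__ = ["encode", "decode", "BinaryDecodeError"]


class BinaryDecodeError(ValueError):
    pass


def encode(obj) -> bytes:
    out = bytearray()
    _enc(obj, out)
    return bytes(out)


def _enc(obj, out: bytearray) -> None:
    if obj is None:
        out.append(0xC0)
    elif obj is True:
        out.append(0xC3)
    elif obj is False:
        out.append(0xC2)
    elif isinstance(obj, int):
        _enc_int(obj, out)
    elif isinstance(obj, float):
        out.append(0xCB)
        out += struct.pack(">d", obj)
    elif isinstance(obj, str):
        data = obj.encode("utf-8")
        n = len(data)
        if n <= 31:
            out.append(0xA0 | n)
        elif n <= 0xFF:
            out += bytes((0xD9, n))
        elif n <= 0xFFFF:
            out.append(0xDA)
            out += struct.pack(">H", n)
        else:
            out.append(0xDB)
            out += struct.pack(">I", n)
        out += data
    elif isinstance(obj, (list, tuple)):
        n = len(obj)
        if n <= 15:
            out.append(0x90 | n)
        elif n <= 0xFFFF:
            out.append(0xDC)
            out += struct.pack(">H", n)
        else:
            out.append(0xDD)
            out += struct.pack(">I", n)
        for item in obj:
            _enc(item, out)
    elif isinstance(obj, dict):
        n = len(obj)
        if n <= 15:
            out.append(0x80 | n)
        elif n <= 0xFFFF:
            out.append(0xDE)
            out += struct.pack(">H", n)
        else:
            out.append(0xDF)
            out += struct.pack(">I", n)
        for key, val in obj.items():
            if not isinstance(key, str):
                raise TypeError(f"map keys must be strings, got {type(key)}")
            _enc(key, out)
            _enc(val, out)
    else:
        raise TypeError(f"cannot encode {type(obj).__name__}")


def _enc_int(v: int, out: bytearray) -> None:
    if 0 <= v <= 0x7F:
        out.append(v)
    elif -32 <= v < 0:
        out.append(v & 0xFF)
    elif 0 <= v <= 0xFF:
        out += bytes((0xCC, v))
    elif 0 <= v <= 0xFFFF:
        out.append(0xCD)
        out += struct.pack(">H", v)
    elif 0 <= v <= 0xFFFFFFFF:
        out.append(0xCE)
        out += struct.pack(">I", v)
    elif 0 <= v <= 0xFFFFFFFFFFFFFFFF:
        out.append(0xCF)
        out += struct.pack(">Q", v)
    elif -0x80 <= v < 0:
        out.append(0xD0)
        out += struct.pack(">b", v)
    elif -0x8000 <= v < 0:
        out.append(0xD1)
        out += struct.pack(">h", v)
    elif -0x80000000 <= v < 0:
        out.append(0xD2)
        out += struct.pack(">i", v)
    elif -0x8000000000000000 <= v < 0:
        out.append(0xD3)
        out += struct.pack(">q", v)
    else:
        raise OverflowError(f"integer out of 64-bit range: {v}")


def decode(data: bytes):
    obj, pos = _dec(data, 0)
    if pos != len(data):
        raise BinaryDecodeError(f"trailing bytes at offset {pos}")
    return obj


def _need(data: bytes, pos: int, n: int) -> None:
    if pos + n > len(data):
        raise BinaryDecodeError(f"truncated payload at offset {pos}")


def _dec(data: bytes, pos: int):
    _need(data, pos, 1)
    b = data[pos]
    pos += 1
    if b <= 0x7F:
        return b, pos
    if b >= 0xE0:
        return b - 0x100, pos
    if 0x80 <= b <= 0x8F:
        return _dec_map(data, pos, b & 0x0F)
    if 0x90 <= b <= 0x9F:
        return _dec_array(data, pos, b & 0x0F)
    if 0xA0 <= b <= 0xBF:
        return _dec_str(data, pos, b & 0x1F)
    if b == 0xC0:
        return None, pos
    if b == 0xC2:
        return False, pos
    if b == 0xC3:
        return True, pos
    if b == 0xCA:
        _need(data, pos, 4)
        return struct.unpack_from(">f", data, pos)[0], pos + 4
    if b == 0xCB:
        _need(data, pos, 8)
        return struct.unpack_from(">d", data, pos)[0], pos + 8
    if b in (0xCC, 0xCD, 0xCE, 0xCF):
        size = 1 << (b - 0xCC)
        _need(data, pos, size)
        return int.from_bytes(data[pos:pos + size], "big"), pos + size
    if b in (0xD0, 0xD1, 0xD2, 0xD3):
        size = 1 << (b - 0xD0)
        _need(data, pos, size)
        return int.from_bytes(data[pos:pos + size], "big", signed=True), pos + size
    if b in (0xD9, 0xDA, 0xDB):
        size = 1 << (b - 0xD9)
        _need(data, pos, size)
        n = int.from_bytes(data[pos:pos + size], "big")
        return _dec_str(data, pos + size, n)
    if b in (0xDC, 0xDD):
        size = 2 << (b - 0xDC)
        _need(data, pos, size)
        n = int.from_bytes(data[pos:pos + size], "big")
        return _dec_array(data, pos + size, n)
    if b in (0xDE, 0xDF):
        size = 2 << (b - 0xDE)
        _need(data, pos, size)
        n = int.from_bytes(data[pos:pos + size], "big")
        return _dec_map(data, pos + size, n)
    raise BinaryDecodeError(f"unsupported type byte 0x{b:02x} at offset {pos - 1}")


def _dec_str(data: bytes, pos: int, n: int):
    _need(data, pos, n)
    try:
        return data[pos:pos + n].decode("utf-8"), pos + n
    except UnicodeDecodeError as err:
        raise BinaryDecodeError(f"invalid UTF-8 at offset {pos}: {err}") from None


def _dec_array(data: bytes, pos: int, n: int):
    out = []
    for _ in range(n):
        item, pos = _dec(data, pos)
        out.append(item)
    return out, pos


def _dec_map(data: bytes, pos: int, n: int):
    out = {}
    for _ in range(n):
        key, pos = _dec(data, pos)
        if not isinstance(key, str):
            raise BinaryDecodeError(f"non-string map key at offset {pos}")
        val, pos = _dec(data, pos)
        out[key] = val
    return out, pos
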