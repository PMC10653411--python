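"""Minimal SAS transport (XPORT version 5) writer.

Emits files readable by ``pandas.read_sas(..., format="xport")`` and by SAS
itself: 80-byte header records, 140-byte NAMESTR variable descriptors, and
observation records with numerics encoded as 8-byte IBM hexadecimal
floating-point doubles.  Only what the synthetic-fixture writer needs is
implemented: one dataset member, numeric and character variables, variable
names up to 8 characters.
"""

from __future__ import annotations

import math
import struct

import pandas as pd

__all__ = ["write_xport"]

_RECORD = 80
_MISSING_NUMERIC = b"." + b"\x00" * 7


def _ieee_to_ibm(value: float) -> bytes:
    """Encode an IEEE double as an 8-byte IBM/360 hexadecimal float."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return _MISSING_NUMERIC
    if value == 0.0:
        return b"\x00" * 8
    sign = 0
    if value < 0:
        sign = 0x80
        value = -value
    mantissa, exp2 = math.frexp(value)  # value = mantissa * 2**exp2, 0.5 <= m < 1
    exp16, rem = divmod(exp2, 4)
    if rem:
        exp16 += 1
        mantissa /= 2.0 ** (4 - rem)
    if not -64 <= exp16 <= 63:
        raise OverflowError(f"value {value!r} outside IBM double range")
    ibm_mantissa = int(mantissa * (1 << 56))
    first = sign | (exp16 + 64)
    return bytes([first]) + ibm_mantissa.to_bytes(7, "big")


def _pad(record: bytes, size: int = _RECORD) -> bytes:
    if len(record) > size:
        raise ValueError("record overflow")
    return record.ljust(size, b" ")


def _header(kind: str) -> bytes:
    text = f"HEADER RECORD*******{kind:<8}HEADER RECORD!!!!!!!" + "0" * 30
    return _pad(text.encode("ascii"))


def _real_header(prefix: str) -> bytes:
    # SAS library/member "first real header": symbol fields then blanks
    fields = f"{prefix:<8}{'SAS':<8}{'SASLIB':<8}{'9.4':<8}{'Linux':<8}"
    return _pad((fields + " " * 24 + "16JAN14:10:10:10").encode("ascii"))


def _namestr(ntype: int, length: int, varnum: int, name: str, position: int) -> bytes:
    # 140-byte NAMESTR entry; label/format fields left blank
    return struct.pack(
        ">hhhh8s40s8shhh2s8shhl52s",
        ntype,  # 1 numeric, 2 character
        0,  # hash
        length,
        varnum,
        name.upper().encode("ascii").ljust(8),
        name.encode("ascii")[:40].ljust(40),
        b" " * 8,  # format name
        0,
        0,
        0,
        b" " * 2,
        b" " * 8,  # informat
        0,
        0,
        position,
        b" " * 52,
    )


def write_xport(df: pd.DataFrame, path, *, dataset_name: str = "DATA") -> None:
    """Write ``df`` as a single-member SAS transport v5 file.

    Character columns are right-padded to their longest value; numeric
    columns become IBM doubles (NaN -> SAS missing).  Variable names longer
    than 8 characters raise, matching the transport format's limit.
    """
    for col in df.columns:
        if len(str(col)) > 8:
            raise ValueError(
                f"column {col!r} exceeds the 8-character transport name limit"
            )
    columns = list(df.columns)
    is_char = {}
    char_len = {}
    for col in columns:
        series = df[col]
        char = series.dtype == object or pd.api.types.is_string_dtype(series)
        is_char[col] = char
        if char:
            char_len[col] = max(
                [len(str(v)) for v in series.dropna()] + [1]
            )

    out = bytearray()
    out += _header("LIBRARY ")
    out += _real_header("SAS")
    out += _pad(b"16JAN14:10:10:10")
    # the member header's tail carries the NAMESTR record size (140)
    member_header = (
        "HEADER RECORD*******MEMBER  HEADER RECORD!!!!!!!"
        + "0" * 17
        + "1600000000"
        + "140"
    )
    out += _pad(member_header.encode("ascii"))
    out += _header("DSCRPTR ")
    member = f"{'SAS':<8}{dataset_name.upper():<8}{'SASDATA':<8}{'9.4':<8}{'Linux':<8}"
    out += _pad((member + " " * 24 + "16JAN14:10:10:10").encode("ascii"))
    out += _pad(b"16JAN14:10:10:10" + b" " * 16 + b" " * 40)

    nvars = len(columns)
    namestr_header = (
        "HEADER RECORD*******NAMESTR HEADER RECORD!!!!!!!"
        + "0" * 6
        + f"{nvars:04d}"
        + "0" * 20
    )
    out += _pad(namestr_header.encode("ascii"))

    position = 0
    namestrs = b""
    for varnum, col in enumerate(columns, start=1):
        if is_char[col]:
            length = char_len[col]
            namestrs += _namestr(2, length, varnum, str(col), position)
        else:
            length = 8
            namestrs += _namestr(1, length, varnum, str(col), position)
        position += length
    obs_len = position
    if len(namestrs) % _RECORD:
        namestrs += b" " * (_RECORD - len(namestrs) % _RECORD)
    out += namestrs
    out += _header("OBS     ")

    body = bytearray()
    for _, row in df.iterrows():
        for col in columns:
            value = row[col]
            if is_char[col]:
                text = "" if pd.isna(value) else str(value)
                body += text.encode("ascii").ljust(char_len[col])
            else:
                body += _ieee_to_ibm(float(value) if not pd.isna(value) else float("nan"))
    if len(body) % _RECORD:
        body += b" " * (_RECORD - len(body) % _RECORD)
    out += body

    with open(path, "wb") as fh:
        fh.write(bytes(out))
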