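"""Shared fixtures and helpers.

Includes a minimal SAS XPORT v5 writer used only to generate synthetic
NHANES-style .xpt fixtures at test time (the package itself reads XPT via
pandas and never writes it). Numeric-only, one dataset member, enough of the
format for pandas.read_sas to consume.
"""

from __future__ import annotations

import math
import struct

import pandas as pd
import pytest

from mni.reference import load_reference_library
from mni.scoring import ScoreShape


@pytest.fixture(scope="session")
def library():
    return load_reference_library()


@pytest.fixture(scope="session")
def shape():
    return ScoreShape()


# -- SAS XPORT v5 writer (test scaffolding only) ---------------------------


def _ibm_double(value: float) -> bytes:
    """IEEE double -> 8-byte IBM System/360 floating point."""
    if value == 0 or math.isnan(value):
        return b"\x00" * 8
    sign = 0x80 if value < 0 else 0x00
    m = abs(value)
    # find base-16 exponent with mantissa in [1/16, 1)
    e16 = math.floor(math.log(m, 16)) + 1
    mant = m / 16.0**e16
    while mant >= 1.0:
        e16 += 1
        mant = m / 16.0**e16
    while mant < 1 / 16:
        e16 -= 1
        mant = m / 16.0**e16
    frac = int(mant * (1 << 56))
    return bytes([sign | (e16 + 64)]) + frac.to_bytes(7, "big")


def _record(text: str) -> bytes:
    return text.ljust(80).encode("ascii")


def write_xpt(df: pd.DataFrame, path, dsname: str = "DATA") -> None:
    """Write a numeric-only DataFrame as a SAS XPORT v5 transport file."""
    stamp = "16SEP26:12:00:00"
    out = bytearray()
    out += _record(
        "HEADER RECORD*******LIBRARY HEADER RECORD!!!!!!!"
        "000000000000000000000000000000"
    )
    out += _record(f"{'SAS':<8}{'SAS':<8}{'SASLIB':<8}{'9.4':<8}{'Linux':<8}" + " " * 24 + stamp)
    out += _record(stamp)
    out += _record(
        "HEADER RECORD*******MEMBER  HEADER RECORD!!!!!!!"
        "000000000000000001600000000140"
    )
    out += _record(
        "HEADER RECORD*******DSCRPTR HEADER RECORD!!!!!!!"
        "000000000000000000000000000000"
    )
    out += _record(
        f"{'SAS':<8}{dsname.upper():<8}{'SASDATA':<8}{'9.4':<8}{'Linux':<8}" + " " * 24 + stamp
    )
    out += _record(stamp + " " * 16 + " " * 40 + " " * 8)
    nvars = df.shape[1]
    out += _record(
        "HEADER RECORD*******NAMESTR HEADER RECORD!!!!!!!"
        f"000000{nvars:04d}00000000000000000000"
    )
    namestr = bytearray()
    for pos, name in enumerate(df.columns):
        namestr += struct.pack(
            ">hhhh8s40s8shhh2s8shhl52s",
            1,  # numeric
            0,
            8,  # length in observation
            pos + 1,
            str(name).upper().encode("ascii").ljust(8),
            str(name).encode("ascii").ljust(40),
            b"BEST".ljust(8),
            0,
            0,
            0,
            b"  ",
            b"".ljust(8),
            0,
            0,
            pos * 8,
            b"".ljust(52),
        )
    pad = (-len(namestr)) % 80
    namestr += b" " * pad
    out += namestr
    out += _record(
        "HEADER RECORD*******OBS     HEADER RECORD!!!!!!!"
        "000000000000000000000000000000"
    )
    body = bytearray()
    for _, row in df.iterrows():
        for v in row:
            body += _ibm_double(float(v))
    body += b" " * ((-len(body)) % 80)
    out += body
    with open(path, "wb") as fh:
        fh.write(bytes(out))
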