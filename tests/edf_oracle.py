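"""Minimal EDF+C writer used as an independent oracle for the EDF reader.

Writes 16-bit EDF with one "EDF Annotations" stream, straight from the
format definition (256-byte fixed header, 256 bytes per signal, int16
little-endian data records, TAL-encoded annotations). Test use only.
"""

from __future__ import annotations

import math

import numpy as np

PHYS_MIN, PHYS_MAX = -1000.0, 1000.0
DIG_MIN, DIG_MAX = -32768, 32767
ANNOT_SAMPLES = 60  # 120 bytes of TALs per record


def _f(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")
    assert len(b) <= width, text
    return b.ljust(width)


def write_edf(path, data_uV: np.ndarray, fs: int, labels: list[str],
              annotations: list[tuple[float, str]] = ()) -> None:
    data_uV = np.atleast_2d(np.asarray(data_uV, dtype=float))
    n_sig = data_uV.shape[0] + 1  # + annotation stream
    n_rec = math.ceil(data_uV.shape[1] / fs)
    padded = np.zeros((data_uV.shape[0], n_rec * fs))
    padded[:, :data_uV.shape[1]] = data_uV
    gain = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.clip(np.round((padded - PHYS_MIN) * gain) + DIG_MIN,
                      DIG_MIN, DIG_MAX).astype("<i2")

    header = b"".join([
        _f("0", 8), _f("X X X X", 80), _f("Startdate 01-JAN-2000 X X X", 80),
        _f("01.01.00", 8), _f("00.00.00", 8),
        _f(str(256 * (n_sig + 1)), 8), _f("EDF+C", 44),
        _f(str(n_rec), 8), _f("1", 8), _f(str(n_sig), 4),
    ])
    sig_labels = labels + ["EDF Annotations"]
    spr = [fs] * data_uV.shape[0] + [ANNOT_SAMPLES]
    fields = [
        [_f(lab, 16) for lab in sig_labels],
        [_f("", 80)] * n_sig,
        [_f("uV", 8)] * data_uV.shape[0] + [_f("", 8)],
        [_f(f"{PHYS_MIN:g}", 8)] * data_uV.shape[0] + [_f("-1", 8)],
        [_f(f"{PHYS_MAX:g}", 8)] * data_uV.shape[0] + [_f("1", 8)],
        [_f(str(DIG_MIN), 8)] * n_sig,
        [_f(str(DIG_MAX), 8)] * n_sig,
        [_f("", 80)] * n_sig,
        [_f(str(n), 8) for n in spr],
        [_f("", 32)] * n_sig,
    ]
    header += b"".join(b"".join(col) for col in fields)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(data_uV.shape[0]):
                fh.write(digital[c, r * fs:(r + 1) * fs].tobytes())
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            for onset, desc in annotations:
                if r <= onset < r + 1:
                    tal += f"+{onset:g}\x14{desc}\x14\x00".encode("ascii")
            fh.write(tal.ljust(2 * ANNOT_SAMPLES, b"\x00"))
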