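"""Minimal single-frame DICOM reader/writer.

Supports only what the package needs: uncompressed Explicit VR Little Endian
files with 16-bit signed/unsigned pixel data, rescale slope/intercept, pixel
spacing, slice geometry and patient id. This is deliberately not a general
DICOM implementation; anything outside this profile raises.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

# tag constants (group, element)
TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_PATIENT_ID = (0x0010, 0x0020)
TAG_SLICE_THICKNESS = (0x0018, 0x0050)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)

_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


@dataclass
class DicomSlice:
    pixels: np.ndarray  # raw stored values (rows, cols)
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing: tuple[float, float]  # (row, col) mm
    slice_thickness: float
    image_position: tuple[float, float, float]
    instance_number: int
    patient_id: str

    @property
    def hu(self) -> np.ndarray:
        return self.pixels.astype(np.float64) * self.rescale_slope + self.rescale_intercept

    @property
    def z(self) -> float:
        return self.image_position[2]


def _encode_element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr != b"UI" else b"\x00"
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _ds(*values: float) -> bytes:
    return "\\".join(f"{v:.10g}" for v in values).encode()


def write_dicom_slice(path: str | Path, pixels: np.ndarray, *,
                      pixel_spacing: tuple[float, float] = (1.0, 1.0),
                      slice_thickness: float = 3.0,
                      image_position: tuple[float, float, float] = (0.0, 0.0, 0.0),
                      instance_number: int = 1,
                      rescale_slope: float = 1.0,
                      rescale_intercept: float = -1024.0,
                      patient_id: str = "anon") -> Path:
    """Write one axial slice of stored (pre-rescale) 16-bit values."""
    path = Path(path)
    pixels = np.asarray(pixels)
    signed = pixels.min() < 0
    arr = pixels.astype("<i2" if signed else "<u2")
    rows, cols = arr.shape

    sop_uid = f"1.2.826.0.1.999999.{instance_number}"
    meta = b"".join([
        _encode_element(0x0002, 0x0001, b"OB", b"\x00\x01"),
        _encode_element(0x0002, 0x0010, b"UI", EXPLICIT_VR_LE.encode()),
        _encode_element(0x0002, 0x0003, b"UI", sop_uid.encode()),
    ])
    meta = _encode_element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta))) + meta

    body = b"".join([
        _encode_element(*TAG_SOP_INSTANCE, b"UI", sop_uid.encode()),
        _encode_element(*TAG_PATIENT_ID, b"LO", patient_id.encode()),
        _encode_element(*TAG_SLICE_THICKNESS, b"DS", _ds(slice_thickness)),
        _encode_element(*TAG_INSTANCE_NUMBER, b"IS", str(instance_number).encode()),
        _encode_element(*TAG_IMAGE_POSITION, b"DS", _ds(*image_position)),
        _encode_element(*TAG_ROWS, b"US", struct.pack("<H", rows)),
        _encode_element(*TAG_COLS, b"US", struct.pack("<H", cols)),
        _encode_element(*TAG_PIXEL_SPACING, b"DS", _ds(*pixel_spacing)),
        _encode_element(*TAG_BITS_ALLOCATED, b"US", struct.pack("<H", 16)),
        _encode_element(*TAG_BITS_STORED, b"US", struct.pack("<H", 16)),
        _encode_element(*TAG_HIGH_BIT, b"US", struct.pack("<H", 15)),
        _encode_element(*TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 1 if signed else 0)),
        _encode_element(*TAG_RESCALE_INTERCEPT, b"DS", _ds(rescale_intercept)),
        _encode_element(*TAG_RESCALE_SLOPE, b"DS", _ds(rescale_slope)),
        _encode_element(*TAG_PIXEL_DATA, b"OW", arr.tobytes()),
    ])

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)
    return path


def read_dicom_slice(path: str | Path) -> DicomSlice:
    data = Path(path).read_bytes()
    if data[128:132] != b"DICM":
        raise ValueError(f"{path}: not a DICOM part-10 file")
    pos = 132
    elements: dict[tuple[int, int], bytes] = {}
    transfer_syntax = EXPLICIT_VR_LE
    while pos + 8 <= len(data):
        group, elem = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", data, pos + 8)
            start = pos + 12
        elif vr.isalpha() and vr.isupper():
            (length,) = struct.unpack_from("<H", data, pos + 6)
            start = pos + 8
        else:
            raise ValueError(
                f"{path}: implicit-VR or unsupported encoding (vr bytes {vr!r}); "
                f"only Explicit VR Little Endian is supported"
            )
        value = data[start : start + length]
        if (group, elem) == (0x0002, 0x0010):
            transfer_syntax = value.rstrip(b"\x00").decode()
        if group != 0x0002:
            elements[(group, elem)] = value
        pos = start + length
    if transfer_syntax != EXPLICIT_VR_LE:
        raise ValueError(f"{path}: unsupported transfer syntax {transfer_syntax}")

    def _get_ds(tag, default=None):
        if tag not in elements:
            if default is None:
                raise ValueError(f"{path}: missing required tag {tag}")
            return default
        return [float(v) for v in elements[tag].decode().strip("\x00 ").split("\\")]

    def _get_us(tag) -> int:
        return struct.unpack("<H", elements[tag][:2])[0]

    rows, cols = _get_us(TAG_ROWS), _get_us(TAG_COLS)
    bits = _get_us(TAG_BITS_ALLOCATED)
    if bits != 16:
        raise ValueError(f"{path}: only 16-bit pixel data supported, got {bits}")
    signed = _get_us(TAG_PIXEL_REPRESENTATION) == 1
    raw = elements[TAG_PIXEL_DATA]
    pixels = np.frombuffer(raw[: rows * cols * 2], dtype="<i2" if signed else "<u2")
    pixels = pixels.reshape(rows, cols).astype(np.int32)

    spacing = _get_ds(TAG_PIXEL_SPACING, [1.0, 1.0])
    position = _get_ds(TAG_IMAGE_POSITION, [0.0, 0.0, 0.0])
    instance = int(elements.get(TAG_INSTANCE_NUMBER, b"0").decode().strip("\x00 ") or 0)
    patient = elements.get(TAG_PATIENT_ID, b"anon").decode().strip("\x00 ")
    return DicomSlice(
        pixels=pixels,
        rescale_slope=_get_ds(TAG_RESCALE_SLOPE, [1.0])[0],
        rescale_intercept=_get_ds(TAG_RESCALE_INTERCEPT, [0.0])[0],
        pixel_spacing=(spacing[0], spacing[1]),
        slice_thickness=_get_ds(TAG_SLICE_THICKNESS, [1.0])[0],
        image_position=(position[0], position[1], position[2]),
        instance_number=instance,
        patient_id=patient,
    )
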