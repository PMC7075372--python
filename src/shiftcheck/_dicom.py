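"""Minimal DICOM codec: explicit VR little endian, the RT tags this tool needs.

Not a general DICOM implementation. Supports Part 10 files (128-byte preamble,
``DICM`` magic, group-2 file meta) with the Explicit VR Little Endian transfer
syntax, nested sequences with defined or undefined lengths, and the value
representations used by CT / RT Structure Set / RT Plan geometry. Files written
here are readable by standard DICOM toolkits.
"""

from __future__ import annotations

import struct
import uuid
from typing import Dict, Iterator, List, Tuple, Union

Tag = Tuple[int, int]

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
RT_STRUCTURE_SET_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"
RT_PLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"

_IMPLEMENTATION_CLASS_UID = "2.25.739841203775702977350281717712"

# keyword -> (tag, VR); the only attributes this codec names.
DICT: Dict[str, Tuple[Tag, str]] = {
    "FileMetaInformationVersion": ((0x0002, 0x0001), "OB"),
    "MediaStorageSOPClassUID": ((0x0002, 0x0002), "UI"),
    "MediaStorageSOPInstanceUID": ((0x0002, 0x0003), "UI"),
    "TransferSyntaxUID": ((0x0002, 0x0010), "UI"),
    "ImplementationClassUID": ((0x0002, 0x0012), "UI"),
    "SpecificCharacterSet": ((0x0008, 0x0005), "CS"),
    "SOPClassUID": ((0x0008, 0x0016), "UI"),
    "SOPInstanceUID": ((0x0008, 0x0018), "UI"),
    "Modality": ((0x0008, 0x0060), "CS"),
    "PatientName": ((0x0010, 0x0010), "PN"),
    "PatientID": ((0x0010, 0x0020), "LO"),
    "SliceThickness": ((0x0018, 0x0050), "DS"),
    "PatientPosition": ((0x0018, 0x5100), "CS"),
    "StudyInstanceUID": ((0x0020, 0x000D), "UI"),
    "SeriesInstanceUID": ((0x0020, 0x000E), "UI"),
    "ImagePositionPatient": ((0x0020, 0x0032), "DS"),
    "ImageOrientationPatient": ((0x0020, 0x0037), "DS"),
    "FrameOfReferenceUID": ((0x0020, 0x0052), "UI"),
    "SamplesPerPixel": ((0x0028, 0x0002), "US"),
    "PhotometricInterpretation": ((0x0028, 0x0004), "CS"),
    "Rows": ((0x0028, 0x0010), "US"),
    "Columns": ((0x0028, 0x0011), "US"),
    "PixelSpacing": ((0x0028, 0x0030), "DS"),
    "BitsAllocated": ((0x0028, 0x0100), "US"),
    "BitsStored": ((0x0028, 0x0101), "US"),
    "HighBit": ((0x0028, 0x0102), "US"),
    "PixelRepresentation": ((0x0028, 0x0103), "US"),
    "StructureSetLabel": ((0x3006, 0x0002), "SH"),
    "ReferencedFrameOfReferenceSequence": ((0x3006, 0x0010), "SQ"),
    "StructureSetROISequence": ((0x3006, 0x0020), "SQ"),
    "ROINumber": ((0x3006, 0x0022), "IS"),
    "ReferencedFrameOfReferenceUID": ((0x3006, 0x0024), "UI"),
    "ROIName": ((0x3006, 0x0026), "LO"),
    "ROIContourSequence": ((0x3006, 0x0039), "SQ"),
    "ContourSequence": ((0x3006, 0x0040), "SQ"),
    "ContourGeometricType": ((0x3006, 0x0042), "CS"),
    "NumberOfContourPoints": ((0x3006, 0x0046), "IS"),
    "ContourData": ((0x3006, 0x0050), "DS"),
    "ReferencedROINumber": ((0x3006, 0x0084), "IS"),
    "RTPlanLabel": ((0x300A, 0x0002), "SH"),
    "BeamSequence": ((0x300A, 0x00B0), "SQ"),
    "BeamNumber": ((0x300A, 0x00C0), "IS"),
    "BeamName": ((0x300A, 0x00C2), "LO"),
    "ControlPointSequence": ((0x300A, 0x0111), "SQ"),
    "ControlPointIndex": ((0x300A, 0x0112), "IS"),
    "IsocenterPosition": ((0x300A, 0x012C), "DS"),
    "PatientSetupSequence": ((0x300A, 0x0180), "SQ"),
    "PatientSetupNumber": ((0x300A, 0x0182), "IS"),
    "PixelData": ((0x7FE0, 0x0010), "OW"),
}

_TAG_TO_VR: Dict[Tag, str] = {tag: vr for tag, vr in DICT.values()}
_TAG_TO_KEYWORD: Dict[Tag, str] = {tag: kw for kw, (tag, _) in DICT.items()}

_ITEM_TAG: Tag = (0xFFFE, 0xE000)
_ITEM_DELIM_TAG: Tag = (0xFFFE, 0xE00D)
_SEQ_DELIM_TAG: Tag = (0xFFFE, 0xE00C)

_LONG_VRS = frozenset({"OB", "OW", "OF", "SQ", "UT", "UN"})
_STRING_VRS = frozenset({"CS", "SH", "LO", "PN", "UI", "DA", "TM", "ST"})

Value = Union[str, bytes, float, int, List[float], List[int], List["Dataset"], None]


class DicomError(ValueError):
    """Malformed or unsupported DICOM input."""


def generate_uid() -> str:
    """A fresh UID under the 2.25 (UUID-derived) root."""
    return f"2.25.{uuid.uuid4().int}"


class Dataset:
    """An ordered mapping of DICOM tags to decoded values.

    Attribute access uses the keywords in :data:`DICT`; missing attributes
    return ``None`` via :meth:`get`.
    """

    def __init__(self) -> None:
        self._elements: Dict[Tag, Value] = {}

    def __setattr__(self, name: str, value) -> None:
        if name.startswith("_"):
            super().__setattr__(name, value)
            return
        if name not in DICT:
            raise AttributeError(f"unknown DICOM keyword {name!r}")
        self._elements[DICT[name][0]] = value

    def __getattr__(self, name: str):
        if name.startswith("_"):
            raise AttributeError(name)
        if name not in DICT:
            raise AttributeError(f"unknown DICOM keyword {name!r}")
        tag = DICT[name][0]
        if tag not in self._elements:
            raise AttributeError(f"dataset has no element {name}")
        return self._elements[tag]

    def get(self, name: str, default=None):
        try:
            return getattr(self, name)
        except AttributeError:
            return default

    def __contains__(self, name: str) -> bool:
        return name in DICT and DICT[name][0] in self._elements

    def tags(self) -> Iterator[Tag]:
        return iter(sorted(self._elements))

    def __eq__(self, other) -> bool:
        return isinstance(other, Dataset) and self._elements == other._elements

    def __repr__(self) -> str:
        parts = []
        for tag in self.tags():
            kw = _TAG_TO_KEYWORD.get(tag, f"({tag[0]:04X},{tag[1]:04X})")
            parts.append(f"{kw}={self._elements[tag]!r}")
        return f"Dataset({', '.join(parts)})"


# --------------------------------------------------------------------------
# encoding


def _encode_value(vr: str, value: Value) -> bytes:
    if vr == "SQ":
        out = bytearray()
        for item in value or []:
            body = _encode_dataset(item)
            out += struct.pack("<HHI", *_ITEM_TAG, len(body))
            out += body
        return bytes(out)
    if vr in ("OB", "OW"):
        data = bytes(value or b"")
        return data + (b"\x00" if len(data) % 2 else b"")
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return b"".join(struct.pack("<H", int(v)) for v in vals)
    if vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return b"".join(struct.pack("<I", int(v)) for v in vals)
    if vr == "DS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(_format_ds(float(v)) for v in vals)
    elif vr == "IS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(str(int(v)) for v in vals)
    elif vr in _STRING_VRS:
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(str(v) for v in vals)
    else:
        raise DicomError(f"cannot encode VR {vr}")
    raw = text.encode("ascii")
    if len(raw) % 2:
        raw += b"\x00" if vr == "UI" else b" "
    return raw


def _format_ds(v: float) -> str:
    # fixed decimal keeps DS within its 16-byte limit for mm-scale geometry
    s = f"{v:.8f}"
    if len(s) > 16:
        s = f"{v:.6g}"
    return s


def _encode_element(tag: Tag, vr: str, value: Value) -> bytes:
    body = _encode_value(vr, value)
    head = struct.pack("<HH", *tag)
    if vr in _LONG_VRS:
        return head + vr.encode("ascii") + b"\x00\x00" + struct.pack("<I", len(body)) + body
    if len(body) > 0xFFFF:
        raise DicomError(f"value too long for short VR {vr}")
    return head + vr.encode("ascii") + struct.pack("<H", len(body)) + body


def _encode_dataset(ds: Dataset) -> bytes:
    out = bytearray()
    for tag in ds.tags():
        vr = _TAG_TO_VR[tag]
        out += _encode_element(tag, vr, ds._elements[tag])
    return bytes(out)


def write_file(path, ds: Dataset, sop_class_uid: str) -> None:
    """Write a Part 10 file (Explicit VR Little Endian)."""
    if "SOPClassUID" not in ds:
        ds.SOPClassUID = sop_class_uid
    if "SOPInstanceUID" not in ds:
        ds.SOPInstanceUID = generate_uid()

    meta = Dataset()
    meta.FileMetaInformationVersion = b"\x00\x01"
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = EXPLICIT_VR_LE
    meta.ImplementationClassUID = _IMPLEMENTATION_CLASS_UID
    meta_bytes = _encode_dataset(meta)

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        # FileMetaInformationGroupLength (0002,0000) UL
        fh.write(struct.pack("<HH", 0x0002, 0x0000) + b"UL" + struct.pack("<H", 4))
        fh.write(struct.pack("<I", len(meta_bytes)))
        fh.write(meta_bytes)
        fh.write(_encode_dataset(ds))


# --------------------------------------------------------------------------
# decoding


class _Reader:
    def __init__(self, data: bytes, pos: int = 0, end: int | None = None):
        self.data = data
        self.pos = pos
        self.end = len(data) if end is None else end

    def remaining(self) -> int:
        return self.end - self.pos

    def take(self, n: int) -> bytes:
        if self.pos + n > self.end:
            raise DicomError("truncated DICOM stream")
        chunk = self.data[self.pos : self.pos + n]
        self.pos += n
        return chunk

    def peek_tag(self) -> Tag:
        g, e = struct.unpack_from("<HH", self.data, self.pos)
        return (g, e)


def _decode_value(vr: str, raw: bytes) -> Value:
    if vr in ("OB", "OW", "UN"):
        return raw
    if vr == "US":
        vals = [struct.unpack_from("<H", raw, i)[0] for i in range(0, len(raw), 2)]
        return vals[0] if len(vals) == 1 else vals
    if vr == "UL":
        vals = [struct.unpack_from("<I", raw, i)[0] for i in range(0, len(raw), 4)]
        return vals[0] if len(vals) == 1 else vals
    text = raw.decode("ascii", errors="replace").rstrip("\x00 ")
    if vr == "DS":
        if not text:
            return []
        try:
            vals = [float(p) for p in text.split("\\")]
        except ValueError as exc:
            raise DicomError(f"malformed DS value {text!r}") from exc
        return vals[0] if len(vals) == 1 else vals
    if vr == "IS":
        if not text:
            return []
        vals = [int(p) for p in text.split("\\")]
        return vals[0] if len(vals) == 1 else vals
    parts = text.split("\\")
    return parts[0] if len(parts) == 1 else parts


def _read_element(r: _Reader) -> Tuple[Tag, Value]:
    g, e = struct.unpack("<HH", r.take(4))
    tag = (g, e)
    vr = r.take(2).decode("ascii")
    if vr in _LONG_VRS:
        r.take(2)
        (length,) = struct.unpack("<I", r.take(4))
    else:
        (length,) = struct.unpack("<H", r.take(2))
    if vr == "SQ":
        return tag, _read_sequence(r, length)
    if length == 0xFFFFFFFF:
        raise DicomError("undefined length outside a sequence is unsupported")
    return tag, _decode_value(vr, r.take(length))


def _read_sequence(r: _Reader, length: int) -> List[Dataset]:
    items: List[Dataset] = []
    end = None if length == 0xFFFFFFFF else r.pos + length
    while True:
        if end is not None and r.pos >= end:
            break
        if r.remaining() < 8:
            if end is None:
                raise DicomError("unterminated sequence")
            break
        g, e = struct.unpack("<HH", r.take(4))
        (item_len,) = struct.unpack("<I", r.take(4))
        if (g, e) == _SEQ_DELIM_TAG:
            break
        if (g, e) != _ITEM_TAG:
            raise DicomError(f"expected sequence item, got ({g:04X},{e:04X})")
        if item_len == 0xFFFFFFFF:
            items.append(_read_item_undefined(r))
        else:
            sub = _Reader(r.data, r.pos, r.pos + item_len)
            items.append(_read_dataset(sub))
            r.pos = sub.end
    return items


def _read_item_undefined(r: _Reader) -> Dataset:
    ds = Dataset()
    while r.remaining() >= 8:
        if r.peek_tag() == _ITEM_DELIM_TAG:
            r.take(8)
            return ds
        tag, value = _read_element(r)
        ds._elements[tag] = value
    raise DicomError("unterminated sequence item")


def _read_dataset(r: _Reader) -> Dataset:
    ds = Dataset()
    while r.remaining() >= 8:
        tag, value = _read_element(r)
        ds._elements[tag] = value
    return ds


def read_file(path) -> Dataset:
    """Read a Part 10 Explicit VR Little Endian file into a :class:`Dataset`."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 132 or data[128:132] != b"DICM":
        raise DicomError(f"{path}: not a DICOM Part 10 file (missing DICM magic)")
    r = _Reader(data, 132)

    # file meta group (always explicit VR LE)
    meta = Dataset()
    while r.remaining() >= 8 and r.peek_tag()[0] == 0x0002:
        tag, value = _read_element(r)
        meta._elements[tag] = value
    ts = meta.get("TransferSyntaxUID")
    if ts is not None and ts != EXPLICIT_VR_LE:
        raise DicomError(f"unsupported transfer syntax {ts}")

    ds = _read_dataset(r)
    ds._elements.update(
        {t: v for t, v in meta._elements.items() if t[0] == 0x0002}
    )
    return ds
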