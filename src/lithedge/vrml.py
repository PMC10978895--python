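"""Minimal VRML97 (.wrl) reader for IndexedFaceSet geometry.

Handles the subset most 3D-scan repositories deposit: one or more
``IndexedFaceSet`` nodes carrying a ``Coordinate { point [...] }`` block and
a ``coordIndex [...]`` list, with polygons separated by ``-1``. Polygons
with more than three vertices are fan-triangulated. Anything fancier
(PROTOs, inline textures, DEF/USE sharing) is out of scope; use OBJ/PLY/STL
for such files.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

__all__ = ["read_vrml", "VrmlParseError"]


class VrmlParseError(ValueError):
    pass


_NUMBER = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


def _strip_comments(text: str) -> str:
    return re.sub(r"#[^\n]*", "", text)


def _bracket_block(text: str, start: int) -> str:
    """Return the contents of the first [...] block at or after ``start``."""
    open_idx = text.find("[", start)
    if open_idx < 0:
        raise VrmlParseError("expected '[' block")
    depth = 0
    for i in range(open_idx, len(text)):
        if text[i] == "[":
            depth += 1
        elif text[i] == "]":
            depth -= 1
            if depth == 0:
                return text[open_idx + 1 : i]
    raise VrmlParseError("unterminated '[' block")


def read_vrml(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse an IndexedFaceSet .wrl file into (vertices, faces)."""
    text = Path(path).read_text(errors="replace")
    header = text.lstrip()[:40]
    if not header.startswith("#VRML") and "IndexedFaceSet" not in text:
        raise VrmlParseError(
            f"{path}: not a VRML file (first bytes: {header[:20]!r})"
        )
    text = _strip_comments(text)

    all_vertices: list[np.ndarray] = []
    all_faces: list[np.ndarray] = []
    offset = 0
    for match in re.finditer(r"IndexedFaceSet", text):
        node_start = match.end()
        coord = re.search(r"Coordinate\s*\{[^[]*point", text[node_start:])
        if coord is None:
            continue
        points_text = _bracket_block(text, node_start + coord.end())
        numbers = np.array(
            [float(t) for t in _NUMBER.findall(points_text)], dtype=float
        )
        if numbers.size % 3 != 0:
            raise VrmlParseError(
                f"{path}: point list length {numbers.size} is not a "
                "multiple of 3"
            )
        vertices = numbers.reshape(-1, 3)

        ci = re.search(r"coordIndex", text[node_start:])
        if ci is None:
            raise VrmlParseError(f"{path}: IndexedFaceSet without coordIndex")
        index_text = _bracket_block(text, node_start + ci.end())
        indices = [int(float(t)) for t in _NUMBER.findall(index_text)]

        faces: list[tuple[int, int, int]] = []
        polygon: list[int] = []
        for idx in indices:
            if idx == -1:
                for k in range(1, len(polygon) - 1):
                    faces.append((polygon[0], polygon[k], polygon[k + 1]))
                polygon = []
            else:
                polygon.append(idx)
        for k in range(1, len(polygon) - 1):  # trailing polygon without -1
            faces.append((polygon[0], polygon[k], polygon[k + 1]))
        if not faces:
            continue
        face_arr = np.asarray(faces, dtype=np.int64)
        if face_arr.max() >= len(vertices):
            raise VrmlParseError(
                f"{path}: coordIndex {face_arr.max()} exceeds point count "
                f"{len(vertices)}"
            )
        all_vertices.append(vertices)
        all_faces.append(face_arr + offset)
        offset += len(vertices)

    if not all_faces:
        raise VrmlParseError(f"{path}: no IndexedFaceSet geometry found")
    return np.vstack(all_vertices), np.vstack(all_faces)
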