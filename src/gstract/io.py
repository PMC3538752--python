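"""Streamline and volume I/O.

Tracts are written either as TrackVis-style .trk files (world-mm RAS
coordinates, identity voxel-to-rasmm affine) with a JSON provenance sidecar,
or as a dependency-free JSON-lines format (one fiber per line) for plain-text
inspection.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np

from .fibers import Fiber, FiberTract


def _sidecar(path: pathlib.Path) -> pathlib.Path:
    return path.with_name(path.name + ".prov.json")


def write_fibers(tract: FiberTract, path) -> None:
    """Write a tract as .trk or .jsonl depending on the extension."""
    path = pathlib.Path(path)
    if path.suffix == ".trk":
        import nibabel as nib
        from nibabel.streamlines import Tractogram

        tg = Tractogram([f.points.astype(np.float32) for f in tract],
                        affine_to_rasmm=np.eye(4))
        nib.streamlines.save(tg, str(path))
        _sidecar(path).write_text(json.dumps(tract.provenance, indent=2))
    elif path.suffix == ".jsonl":
        with path.open("w") as fh:
            fh.write(json.dumps({"provenance": tract.provenance}) + "\n")
            for f in tract:
                rec = {"points": np.asarray(f.points, np.float32).tolist(),
                       "provenance": f.provenance}
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unsupported fiber format {path.suffix!r}")


def read_fibers(path) -> FiberTract:
    """Read a tract written by :func:`write_fibers`."""
    path = pathlib.Path(path)
    if path.suffix == ".trk":
        import nibabel as nib

        trk = nib.streamlines.load(str(path))
        fibers = [Fiber(np.asarray(s, float)) for s in trk.streamlines]
        prov = {}
        side = _sidecar(path)
        if side.exists():
            prov = json.loads(side.read_text())
        return FiberTract(fibers, prov)
    if path.suffix == ".jsonl":
        fibers = []
        prov = {}
        with path.open() as fh:
            for lineno, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(
                        f"malformed fiber record at line {lineno + 1} "
                        f"of {path}") from exc
                if lineno == 0 and "points" not in rec:
                    prov = rec.get("provenance", {})
                    continue
                fibers.append(Fiber(np.asarray(rec["points"], float),
                                    rec.get("provenance", {})))
        return FiberTract(fibers, prov)
    raise ValueError(f"unsupported fiber format {path.suffix!r}")


def load_mask(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def load_tensor_field(path):
    """6-component NIfTI -> TensorField."""
    import nibabel as nib

    from .tensor_field import TensorField

    img = nib.load(str(path))
    return TensorField(np.asarray(img.get_fdata()), affine=img.affine)
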