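"""Plain-text readers/writers for the pipeline's intermediate products."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .shape import FourierShape

__all__ = [
    "write_shapes_csv", "read_shapes_csv", "write_contours_csv",
    "read_contours_csv", "write_flow_csv", "write_trajectories_csv",
    "write_field_csv", "write_harmonics_json", "load_config", "save_config",
    "read_stack", "write_stack",
]


def read_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF movie as a (frames, y, x) float array."""
    import tifffile

    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def write_stack(frames, path) -> None:
    """Write an image sequence as a multi-page float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def write_shapes_csv(shapes: list[FourierShape], path,
                     cm: np.ndarray = None) -> None:
    rows = []
    for i, s in enumerate(shapes):
        row = {"frame": s.frame_index}
        row.update({f"a{k}": s.a[k] for k in range(len(s.a))})
        row["orientation_rad"] = s.orientation
        row["cm_x"], row["cm_y"] = (cm[i] if cm is not None else (0.0, 0.0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_shapes_csv(path) -> list[FourierShape]:
    df = pd.read_csv(path)
    acols = sorted((c for c in df.columns if c.startswith("a") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    return [FourierShape(a=row[acols].to_numpy(dtype=float),
                         orientation=float(row.get("orientation_rad", 0.0)),
                         frame_index=int(row["frame"]))
            for _, row in df.iterrows()]


def write_contours_csv(contours, path) -> None:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append({"frame": c.frame_index, "point_index": i,
                         "x_px": x, "y_px": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours_csv(path):
    from .contours import Contour

    df = pd.read_csv(path)
    out = []
    for f, grp in df.groupby("frame"):
        grp = grp.sort_values("point_index")
        out.append(Contour(points=grp[["x_px", "y_px"]].to_numpy(),
                           frame_index=int(f)))
    return out


def write_flow_csv(grids, path) -> None:
    pd.concat([g.to_dataframe(frame=i) for i, g in enumerate(grids)],
              ignore_index=True).to_csv(path, index=False)


def write_trajectories_csv(trajectories, path) -> None:
    rows = []
    for sid, tr in enumerate(trajectories):
        for t, x, z in zip(tr.t, tr.x, tr.z):
            rows.append({"seed_id": sid, "t": t, "x": x, "z": z})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_field_csv(field, path) -> None:
    field.to_dataframe().to_csv(path, index=False)


def write_harmonics_json(solution, path) -> None:
    data = {
        "radius": solution.radius,
        "viscosity_mPa_s": solution.viscosity,
        "c_phi": np.asarray(solution.c_phi).tolist(),
        "c_p": np.asarray(solution.c_p).tolist(),
    }
    Path(path).write_text(json.dumps(data, indent=1))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
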