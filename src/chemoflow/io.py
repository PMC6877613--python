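"""HDF5 / TIFF / CSV plumbing shared by the library and the CLI."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .fourier_motility import DICF, ImageStack, ISFFit
    from .rod_dynamics import SimulationConfig, Trajectories


def _config_dict(config) -> dict:
    d = dataclasses.asdict(config)
    out = {}
    for k, v in d.items():
        if v is None or isinstance(v, (int, float, str, bool)):
            out[k] = v
        elif isinstance(v, dict):
            out[k] = v
        else:
            out[k] = str(v)
    return out


def config_hash(config) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def trajectories_to_hdf5(traj: "Trajectories", path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        cfg = f.create_group("config")
        for k, v in _config_dict(traj.config).items():
            if isinstance(v, dict):
                cfg.attrs[k] = json.dumps(v)
            else:
                cfg.attrs[k] = "null" if v is None else v
        cfg.attrs["config_hash"] = config_hash(traj.config)
        g = f.create_group("trajectories")
        T = len(traj.times)
        chunk_t = max(1, min(T, 64))
        n = traj.theta.shape[1]
        g.create_dataset("time", data=traj.times)
        g.create_dataset("position", data=traj.positions,
                         chunks=(chunk_t, n, 2))
        g.create_dataset("unwrapped_x", data=traj.unwrapped_x,
                         chunks=(chunk_t, n))
        g.create_dataset("theta", data=traj.theta, chunks=(chunk_t, n))
        g.create_dataset("motor_state", data=traj.motor_state,
                         chunks=(chunk_t, n))
        g.create_dataset("velocity", data=traj.velocity,
                         chunks=(chunk_t, n, 2))
        g.create_dataset("v_i", data=traj.v_i)
        p = f.create_group("pathway")
        p.create_dataset("methylation", data=traj.methylation,
                         chunks=(chunk_t, n))
        p.create_dataset("activity", data=traj.activity, chunks=(chunk_t, n))


def trajectories_from_hdf5(path) -> "Trajectories":
    import h5py

    from .chemo_pathway import PathwayParams
    from .rod_dynamics import SimulationConfig, Trajectories
    from .synthetic_data import GradientSpec

    with h5py.File(path, "r") as f:
        attrs = dict(f["config"].attrs)
        attrs.pop("config_hash", None)
        pathway = attrs.pop("pathway", None)
        gradient = attrs.pop("gradient", None)
        kwargs = {}
        for k, v in attrs.items():
            kwargs[k] = None if (isinstance(v, str) and v == "null") else v
        for key in ("n_rods",):
            if kwargs.get(key) is not None:
                kwargs[key] = int(kwargs[key])
        for key in ("hydrodynamics_on", "steric_on"):
            kwargs[key] = bool(kwargs[key])
        kwargs["seed"] = int(kwargs["seed"])
        if pathway is not None and not (isinstance(pathway, str)
                                        and pathway == "null"):
            kwargs["pathway"] = PathwayParams(**json.loads(pathway))
        if gradient is not None and not (isinstance(gradient, str)
                                         and gradient == "null"):
            kwargs["gradient"] = GradientSpec(**json.loads(gradient))
        config = SimulationConfig(**kwargs)
        g = f["trajectories"]
        return Trajectories(
            times=g["time"][:], positions=g["position"][:],
            unwrapped_x=g["unwrapped_x"][:], theta=g["theta"][:],
            motor_state=g["motor_state"][:], v_i=g["v_i"][:],
            velocity=g["velocity"][:],
            methylation=f["pathway"]["methylation"][:],
            activity=f["pathway"]["activity"][:], config=config)


def stack_to_tiff(stack: "ImageStack", path) -> None:
    import tifffile

    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     metadata={"px_size_um": stack.px_size,
                               "frame_rate": stack.frame_rate})


def stack_from_tiff(path, px_size=1.4, frame_rate=100.0) -> "ImageStack":
    import tifffile

    from .fourier_motility import ImageStack

    frames = tifffile.imread(path)
    return ImageStack(frames=np.asarray(frames, dtype=np.float32),
                      px_size=px_size, frame_rate=frame_rate)


def stack_to_hdf5(stack: "ImageStack", path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=stack.frames.astype(np.float32))
        d.attrs["px_size"] = stack.px_size
        d.attrs["frame_rate"] = stack.frame_rate


def stack_from_hdf5(path) -> "ImageStack":
    import h5py

    from .fourier_motility import ImageStack

    with h5py.File(path, "r") as f:
        d = f["frames"]
        return ImageStack(frames=d[:], px_size=float(d.attrs["px_size"]),
                          frame_rate=float(d.attrs["frame_rate"]))


def dicf_to_csv(dicf: "DICF", fit: "ISFFit | None", path) -> None:
    import pandas as pd

    df = pd.DataFrame({"q_px": dicf.q_px, "q_um": dicf.q_um,
                       "a0": dicf.a0, "a1": dicf.a1})
    if fit is not None:
        per_q = pd.DataFrame({"q_px": fit.q_fit_px, "v0": fit.v0_q,
                              "alpha": fit.alpha_q, "D": fit.D_q,
                              "Z": fit.Z_q})
        df = df.merge(per_q, on="q_px", how="left")
    df.to_csv(path, index=False)


def spectrum_to_csv(spectrum, baseline, path) -> None:
    import pandas as pd

    data = {"q": spectrum.q, "E": spectrum.E}
    if baseline is not None:
        data["E_baseline"] = baseline.E
    pd.DataFrame(data).to_csv(path, index=False)
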