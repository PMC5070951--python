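"""HDF5 / TSV container I/O for studies, coupling tensors and graphs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .parcels import ParcelMeta
from .synth import CouplingSpec, StudyBehavior, StudyConfig, SyntheticStudy

__all__ = [
    "save_study",
    "load_study",
    "save_coupling",
    "load_coupling",
    "statgraph_frame",
    "write_tsv",
    "file_sha256",
]


def save_study(path: str | Path, study: SyntheticStudy) -> None:
    """Write a synthetic study to HDF5 with a JSON config sidecar.

    Layout: /series [subject, load, trial, parcel, sample], /truth as a
    table, /behavior/hit_rate, /meta/* arrays; the study config is
    stored both as a root attribute and as ``<path>.json``.
    """
    path = Path(path)
    cfg_json = json.dumps(dataclasses.asdict(study.config))
    with h5py.File(path, "w") as h5:
        h5.create_dataset("series", data=study.series, compression="gzip", compression_opts=1)
        h5["series"].attrs["axes"] = "subject,load,trial,parcel,sample"
        tr = h5.create_group("truth")
        specs = study.truth
        tr.create_dataset("source_parcel", data=[t.source_parcel for t in specs])
        tr.create_dataset("target_parcel", data=[t.target_parcel for t in specs])
        tr.create_dataset("f_low", data=[t.f_low for t in specs])
        tr.create_dataset("ratio_m", data=[t.ratio_m for t in specs])
        tr.create_dataset("coupling_factor", data=[t.coupling_factor for t in specs])
        tr.create_dataset("load_slope", data=[t.load_slope for t in specs])
        tr.create_dataset("retention_only", data=[t.retention_only for t in specs])
        tr.create_dataset(
            "kind", data=np.array([t.kind for t in specs], dtype=h5py.string_dtype())
        )
        h5.create_dataset("behavior/hit_rate", data=study.behavior.hit_rate)
        if study.subject_gain is not None:
            h5.create_dataset("behavior/subject_gain", data=study.subject_gain)
        m = h5.create_group("meta")
        meta = study.parcel_meta
        for name in ("fine_to_coarse", "coarse_to_system", "fidelity", "cross_talk",
                     "spread", "excluded", "crosstalk_matrix"):
            m.create_dataset(name, data=getattr(meta, name))
        h5.attrs["config"] = cfg_json
    path.with_suffix(path.suffix + ".json").write_text(cfg_json)


def load_study(path: str | Path) -> SyntheticStudy:
    with h5py.File(path, "r") as h5:
        cfg = StudyConfig(**_tuplify(json.loads(h5.attrs["config"])))
        series = h5["series"][...]
        tr = h5["truth"]
        truth = [
            CouplingSpec(
                source_parcel=int(tr["source_parcel"][i]),
                target_parcel=int(tr["target_parcel"][i]),
                f_low=float(tr["f_low"][i]),
                ratio_m=int(tr["ratio_m"][i]),
                coupling_factor=float(tr["coupling_factor"][i]),
                kind=tr["kind"][i].decode(),
                load_slope=float(tr["load_slope"][i]),
                retention_only=bool(tr["retention_only"][i]),
            )
            for i in range(tr["source_parcel"].shape[0])
        ]
        behavior = StudyBehavior(hit_rate=h5["behavior/hit_rate"][...])
        gain = h5["behavior/subject_gain"][...] if "behavior/subject_gain" in h5 else None
        m = h5["meta"]
        meta = ParcelMeta(
            fine_to_coarse=m["fine_to_coarse"][...],
            coarse_to_system=m["coarse_to_system"][...],
            fidelity=m["fidelity"][...],
            cross_talk=m["cross_talk"][...],
            spread=m["spread"][...],
            excluded=m["excluded"][...],
            crosstalk_matrix=m["crosstalk_matrix"][...],
        )
    return SyntheticStudy(series=series, truth=truth, behavior=behavior,
                          parcel_meta=meta, config=cfg, subject_gain=gain)


def _tuplify(d: dict) -> dict:
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    return d


def save_coupling(path: str | Path, tensors: dict) -> None:
    """Persist coupling tensors: {metric: {(f_low, m): array}} plus extras.

    Dataset names encode the frequency pair: /<metric>/f<flow>_m<m>.
    Scalar-keyed groups (e.g. per-frequency amplitudes) use /amp/f<f>.
    """
    with h5py.File(path, "w") as h5:
        for metric, entries in tensors.items():
            g = h5.create_group(metric)
            for key, arr in entries.items():
                if isinstance(key, tuple):
                    name = f"f{key[0]:g}_m{key[1]}"
                else:
                    name = f"f{key:g}"
                g.create_dataset(name, data=arr)


def load_coupling(path: str | Path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as h5:
        for metric in h5:
            out[metric] = {}
            for name in h5[metric]:
                body = name[1:]
                if "_m" in body:
                    f_s, m_s = body.split("_m")
                    key: tuple | float = (float(f_s), int(m_s))
                else:
                    key = float(body)
                out[metric][key] = h5[metric][name][...]
    return out


def statgraph_frame(graph, edge_index: np.ndarray) -> pd.DataFrame:
    """StatGraph as a TSV-ready edge table.

    ``edge_index`` is (n_edges, 2) of (parcel_low, parcel_high).
    """
    return pd.DataFrame(
        {
            "parcel_low": edge_index[:, 0],
            "parcel_high": edge_index[:, 1],
            "effect": graph.effect_size,
            "p": graph.p_value,
            "significant": graph.significant.astype(int),
            "sign": graph.sign,
        }
    )


def write_tsv(path: str | Path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
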