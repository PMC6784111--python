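"""Readers and writers for the delimited assay-table formats.

Column conventions:
  sensorgram  time_s, response_RU, conc_M, phase {association, dissociation}
  melt curve  temp_C, fluorescence
  SEC trace   time_min, mAU
  PK table    animal_id, dose_mg_per_kg, time_h, conc_mg_per_L
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dsf import MeltCurve
from .pk import PKDataset
from .sec import ChromatogramTrace
from .spr import Sensorgram

SEP = "\t"


def read_fasta(path) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: List[Tuple[str, str]]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path), "fasta",
    )


def write_sensorgrams(path, sensorgrams: List[Sensorgram]) -> None:
    frames = []
    for sg in sensorgrams:
        frames.append(pd.DataFrame({
            "time_s": sg.time,
            "response_RU": sg.response,
            "conc_M": sg.concentration,
            "phase": np.where(sg.time <= sg.t_stop, "association", "dissociation"),
        }))
    pd.concat(frames).to_csv(path, sep=SEP, index=False)


def read_sensorgrams(path) -> List[Sensorgram]:
    df = pd.read_csv(path, sep=SEP)
    out = []
    for conc, grp in df.groupby("conc_M", sort=True):
        assoc = grp[grp["phase"] == "association"]
        t_stop = float(assoc["time_s"].max())
        out.append(Sensorgram(
            grp["time_s"].to_numpy(), grp["response_RU"].to_numpy(),
            float(conc), t_stop,
        ))
    return out


def write_melt_curve(path, curve: MeltCurve) -> None:
    pd.DataFrame({"temp_C": curve.temperature,
                  "fluorescence": curve.fluorescence}).to_csv(
        path, sep=SEP, index=False)


def read_melt_curve(path) -> MeltCurve:
    df = pd.read_csv(path, sep=SEP)
    return MeltCurve(df["temp_C"].to_numpy(), df["fluorescence"].to_numpy())


def write_trace(path, trace: ChromatogramTrace) -> None:
    pd.DataFrame({"time_min": trace.time, "mAU": trace.absorbance}).to_csv(
        path, sep=SEP, index=False)


def read_trace(path) -> ChromatogramTrace:
    df = pd.read_csv(path, sep=SEP)
    return ChromatogramTrace(df["time_min"].to_numpy(), df["mAU"].to_numpy())


def write_pk_dataset(path, data: PKDataset) -> None:
    rows = []
    for animal in range(data.concentrations.shape[0]):
        for j, t in enumerate(data.times):
            rows.append({
                "animal_id": f"{data.antibody_id}-a{animal + 1}",
                "dose_mg_per_kg": data.dose_mg_per_kg,
                "time_h": t,
                "conc_mg_per_L": data.concentrations[animal, j],
            })
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def read_pk_dataset(path, antibody_id: str = "") -> PKDataset:
    df = pd.read_csv(path, sep=SEP)
    times = np.sort(df["time_h"].unique())
    animals = sorted(df["animal_id"].unique())
    conc = np.empty((len(animals), len(times)))
    for i, animal in enumerate(animals):
        sub = df[df["animal_id"] == animal].sort_values("time_h")
        conc[i] = sub["conc_mg_per_L"].to_numpy()
    return PKDataset(
        antibody_id=antibody_id or str(animals[0]).rsplit("-a", 1)[0],
        dose_mg_per_kg=float(df["dose_mg_per_kg"].iloc[0]),
        times=times, concentrations=conc,
    )
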