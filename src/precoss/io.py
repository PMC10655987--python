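"""Serialization of corpora and recognition traces.

Corpora are stored in an HDF5 container (one group per sentence holding
the spectrogram, envelope, labels and boundaries, plus the inventory
patterns at the root) together with a delimited-text label table. Traces
share the same container layout on the 1 kHz time base.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .corpus import SentenceStimulus, StimulusArrays, SyllableInventory, SyllableTemplate
from .inference import RecognitionTrace


def save_corpus(
    path, inventory: SyllableInventory, corpus, label_table_path=None
) -> None:
    """Write inventory + sentences to HDF5 and (optionally) a CSV label table."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_syllables"] = inventory.n_syllables
        f.attrs["seed"] = inventory.seed
        f.create_dataset("inventory/patterns", data=inventory.stacked())
        for i, (sent, arrays) in enumerate(corpus):
            g = f.create_group(f"sentences/{i:04d}")
            g.attrs["seed"] = sent.seed
            g.create_dataset("spectrogram", data=arrays.spectrogram)
            g.create_dataset("envelope", data=arrays.envelope)
            g.create_dataset("syllable_ids", data=np.array(sent.syllable_ids))
            g.create_dataset("onsets_ms", data=sent.onsets_ms)
            g.create_dataset("offsets_ms", data=sent.offsets_ms)
    if label_table_path is not None:
        rows = []
        for i, (sent, _) in enumerate(corpus):
            for pos, (sid, on, off) in enumerate(
                zip(sent.syllable_ids, sent.onsets_ms, sent.offsets_ms)
            ):
                rows.append((i, pos, sid, int(on), int(off)))
        pd.DataFrame(
            rows,
            columns=["sentence_id", "position", "syllable_id", "onset_ms", "offset_ms"],
        ).to_csv(label_table_path, index=False)


def load_corpus(path):
    """Read a corpus container back into (inventory, [(sentence, arrays)])."""
    with h5py.File(path, "r") as f:
        patterns = f["inventory/patterns"][()]
        templates = tuple(
            SyllableTemplate(id=i + 1, pattern=p) for i, p in enumerate(patterns)
        )
        inventory = SyllableInventory(
            templates=templates,
            seed=int(f.attrs["seed"]),
            n_syllables=int(f.attrs["n_syllables"]),
        )
        corpus = []
        if "sentences" in f:
            for key in sorted(f["sentences"]):
                g = f[f"sentences/{key}"]
                sent = SentenceStimulus(
                    syllable_ids=tuple(int(x) for x in g["syllable_ids"][()]),
                    onsets_ms=g["onsets_ms"][()],
                    offsets_ms=g["offsets_ms"][()],
                    seed=int(g.attrs["seed"]),
                )
                arrays = StimulusArrays(
                    spectrogram=g["spectrogram"][()], envelope=g["envelope"][()]
                )
                corpus.append((sent, arrays))
    return inventory, corpus


def save_trace(path, trace: RecognitionTrace) -> None:
    """Write a recognition trace to HDF5 (aligned 1 kHz time base)."""
    with h5py.File(path, "w") as f:
        f.attrs["variant"] = trace.variant
        f.attrs["psi"] = trace.psi
        f.attrs["status"] = trace.status
        f.attrs["n_state_variables"] = trace.n_state_variables
        for name in (
            "omega",
            "softmax_omega",
            "y",
            "z",
            "z_pe",
            "gamma_pe",
            "input_pe",
            "logv_omega",
            "logv_gamma",
            "h",
            "reset_gate",
            "markers",
        ):
            f.create_dataset(name, data=getattr(trace, name))


def window_summary(trace: RecognitionTrace) -> pd.DataFrame:
    """Compact per-window table: start/end, winning syllable, mean belief."""
    from .metrics import recognized_sequence

    M, _ = recognized_sequence(trace.softmax_omega, trace.markers)
    rows = []
    k = 0
    for i in range(len(trace.markers) - 1):
        a, b = int(trace.markers[i]), int(trace.markers[i + 1])
        if b <= a:
            continue
        winner = int(np.argmax(M[k])) + 1
        rows.append((a, b, winner, float(M[k][winner - 1])))
        k += 1
    return pd.DataFrame(rows, columns=["start_ms", "end_ms", "winner_id", "mean_softmax"])
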