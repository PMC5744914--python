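"""Plain-text serialization for spike-train ensembles.

No domain-standard container exists for multi-fiber spike trains, so the
dialect is deliberately simple and documented here:

* ``<stem>.txt`` -- two tab-separated columns ``fiber_id`` and ``time_s``,
  one spike per line, fibers labelled ``E0..`` (excitatory) and ``I0..``
  (inhibitory); times printed with 17 significant digits so float64 values
  round-trip exactly.  Lines starting with ``#`` are comments.
* ``<stem>.json`` -- ensemble header: stimulus, fiber configuration, seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .input_stage import (
    InputEnsembleConfig,
    SpikeTrain,
    SpikeTrainSet,
    StimulusSpec,
)

__all__ = ["save_ensemble", "load_ensemble"]


def save_ensemble(ensemble: SpikeTrainSet, stem) -> None:
    """Write ``<stem>.txt`` (spikes) and ``<stem>.json`` (header)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    with open(stem.with_suffix(".txt"), "w") as fh:
        fh.write("# fiber_id\ttime_s\n")
        for prefix, trains in (("E", ensemble.excitatory), ("I", ensemble.inhibitory)):
            for m, train in enumerate(trains):
                for t in train.times:
                    fh.write(f"{prefix}{m}\t{t:.17g}\n")
    header = {
        "stimulus": ensemble.stimulus.to_dict() if ensemble.stimulus else None,
        "config": ensemble.config.to_dict(),
        "seed": ensemble.seed,
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(header, fh, indent=1)


def load_ensemble(stem) -> SpikeTrainSet:
    """Read an ensemble written by :func:`save_ensemble`."""
    stem = Path(stem)
    with open(stem.with_suffix(".json")) as fh:
        header = json.load(fh)
    config = InputEnsembleConfig.from_dict(header["config"])
    stim = header["stimulus"]
    stimulus = StimulusSpec.from_dict(stim) if stim is not None else None

    ex = [[] for _ in range(config.m_ex)]
    inh = [[] for _ in range(config.m_inh)]
    with open(stem.with_suffix(".txt")) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fiber, t = line.split("\t")
            idx = int(fiber[1:])
            (ex if fiber[0] == "E" else inh)[idx].append(float(t))
    return SpikeTrainSet(
        excitatory=[SpikeTrain(np.asarray(t)) for t in ex],
        inhibitory=[SpikeTrain(np.asarray(t)) for t in inh],
        stimulus=stimulus,
        config=config,
        seed=header["seed"],
    )
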