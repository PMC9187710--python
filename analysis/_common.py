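"""Shared helpers for the analysis drivers."""

import json
from pathlib import Path

from dynclicks.accumulation import ModelParams


def load_agent_theta(path) -> ModelParams:
    """Generative agent parameters recorded by 01_simulate.py."""
    rec = json.loads(Path(path).read_text())["agent"]
    return ModelParams(**rec)


def load_fit_theta(path) -> ModelParams:
    """Fitted parameters written by 03_fit.py."""
    rec = json.loads(Path(path).read_text())["theta_hat"]
    rec = {k: v for k, v in rec.items() if k != "click_noise"}
    return ModelParams(**rec)
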