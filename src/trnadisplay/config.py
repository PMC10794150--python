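"""Single-YAML run configuration covering every pipeline stage.

Sections (all optional except ``design`` when a reference is not generated):

* ``design``   — reference (sequence, FASTA path, or null for a seeded random
  ORF), positions, schemes, anchor_length, amplicon_bounds.
* ``simulate`` — truth and plan parameters (n_variants, frac_active, ...,
  replicates, reads_per_sample, error_rate, read_length).
* ``readprep`` — min_overlap, max_mismatch_frac, max_anchor_mismatches.
* ``scoring``  — placeholder_counts, enrichment_min, selectivity_min,
  dispersion_max, exclude_stops.
* ``report``   — plot format and axes.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError
from .sim_select import random_orf
from .variant_model import LibraryDesign, design_from_config

DEFAULT_CONFIG: dict = {
    "design": {
        # null reference -> seeded random ORF of `orf_codons` codons
        "reference": None,
        "orf_codons": 40,
        "positions": [10, 13, 25],
        "schemes": ["NNK", "NNK", "NNK"],
        "anchor_length": 12,
        "amplicon_bounds": None,
    },
    "simulate": {
        "n_variants": 1000,
        "frac_active": 0.05,
        "frac_promiscuous": 0.01,
        "activity_beta": [2.0, 2.0],
        "background_beta": [2.0, 8.0],
        "abundance_sigma": 1.0,
        "epsilon": 0.01,
        "replicates": 3,
        "input_replicates": None,
        "reads_per_sample": 200000,
        "error_rate": 0.001,
        "read_length": None,
        "capture_jitter_sigma": 0.0,
        "monomer_label": "ncM",
    },
    "readprep": {
        "min_overlap": 20,
        "max_mismatch_frac": 0.1,
        "max_anchor_mismatches": 1,
    },
    "scoring": {
        "placeholder_counts": 0.95,
        "enrichment_min": 5.0,
        "selectivity_min": 10.0,
        "dispersion_max": 1.0,
        "exclude_stops": True,
    },
    "report": {
        "plot_format": "svg",
        "x_column": "selectivity",
        "y_column": "enrichment",
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, filling unspecified keys from the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError(f"config {path} must be a mapping of sections")
    for section, values in doc.items():
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if values is None:
            continue
        if not isinstance(values, Mapping):
            raise ConfigError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ConfigError(f"unknown key {key!r} in section {section!r}")
            cfg[section][key] = val
    return cfg


def design_from_run_config(cfg: dict, seed: int, base_dir: str | Path = ".") -> LibraryDesign:
    """Materialise the design section, generating a random ORF if needed."""
    d = dict(cfg["design"])
    if d.get("reference") is None:
        d["reference"] = random_orf(int(d.get("orf_codons", 40)), seed=seed)
    d.pop("orf_codons", None)
    return design_from_config(d, base_dir=base_dir)
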