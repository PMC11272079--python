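"""Pipeline configuration: thresholds and seeds with documented defaults.

A YAML file with any subset of the keys below overrides the defaults;
unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import yaml

DEFAULTS: dict = {
    # sentinel classification
    "low_div_threshold": 0.001,
    # saturation cap on per-branch dN and dS
    "saturation_cap": 1.5,
    # fold-over-genome-median screens
    "signalc_fold": 1.5,
    "bulksg_fold": 2.2,
    # absolute cuts
    "rapid_omega_cut": 0.20,
    "hawaiian_absolute_cut": 0.33,
    "hawaiian_fold_cut": 1.5,
    # expression
    "tau_threshold": 0.90,
    "cluster_metric": "euclidean",
    # significance gates
    "singlec_p": 0.05,
    "bulksg_p": 0.01,
    "branch_site_alpha": 0.05,
    # PGLS sentinel imputation
    "gt1_imputed_omega": 1.5,
    "lowdiv_imputed_omega": 0.0,
    "max_gt1_branches": 1,
    # optimizer
    "n_restarts": 2,
    "seed": 0,
}


def load_config(path=None) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
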