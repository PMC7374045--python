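"""Structured-text (YAML) model configuration.

A model config bundles the Boolean networks (inline rule text or file
paths), node-kind annotations, cytokine transport parameters, secretion and
receptor wiring, mutation rules, tissue geometry and run lengths — enough to
reconstruct a :class:`tmesim.model.TMEModel` on another machine.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .boolnet import parse_rules
from .diffusion import CytokineParams
from .model import MutationRule, ReceptorRule, SecretionRule, TMEModel
from .tissue import TissueConfig

__all__ = ["load_model", "save_model", "model_to_dict", "model_from_dict"]


def model_to_dict(model: TMEModel) -> dict:
    return {
        "name": model.name,
        "q": model.q,
        "h": model.h,
        "cancer_type": model.cancer_type,
        "networks": {
            ct: {
                "rules": net.to_text(),
                "receptors": list(net.receptors),
                "phenotypes": list(net.phenotype_nodes),
                "secretion_nodes": dict(net.secretion_nodes),
            } for ct, net in model.networks.items()
        },
        "cytokines": [
            {"name": c.name, "D": c.D, "gamma_D": c.gamma_D}
            for c in model.cytokines.values()
        ],
        "secretion": [
            {"cell_type": r.cell_type, "cytokine": r.cytokine,
             "rate": r.rate, "node": r.node} for r in model.secretion
        ],
        "receptors": [
            {"cell_type": r.cell_type, "cytokine": r.cytokine,
             "node": r.node, "threshold": r.threshold} for r in model.receptors
        ],
        "mutations": [
            {"gene": m.gene, "value": m.value, "alpha": m.alpha,
             "cell_type": m.cell_type} for m in model.mutations
        ],
        "tissue": {
            "L": model.tissue.L, "rho": model.tissue.rho,
            "r_C": model.tissue.r_C, "s": model.tissue.s,
            "R_ex": model.tissue.R_ex,
            "rho_max_multiplier": model.tissue.rho_max_multiplier,
            "cancer_type": model.tissue.cancer_type,
            "stromal_fractions": dict(model.tissue.stromal_fractions),
            "fixed_n": model.tissue.fixed_n,
        },
    }


def model_from_dict(cfg: dict, base_dir: Path | None = None) -> TMEModel:
    networks = {}
    for ct, spec in cfg["networks"].items():
        if "rules" in spec:
            text = spec["rules"]
        else:
            path = Path(spec["rules_file"])
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            text = path.read_text()
        networks[ct] = parse_rules(
            text, name=ct,
            receptors=spec.get("receptors", ()),
            phenotype_nodes=spec.get("phenotypes", ()),
            secretion_nodes=spec.get("secretion_nodes", {}),
        )
    cytokines = [CytokineParams(**c) for c in cfg["cytokines"]]
    secretion = [SecretionRule(**r) for r in cfg.get("secretion", [])]
    receptors = [ReceptorRule(**r) for r in cfg.get("receptors", [])]
    mutations = [MutationRule(**m) for m in cfg.get("mutations", [])]
    tissue = TissueConfig(**cfg["tissue"])
    return TMEModel(networks=networks, cytokines=cytokines, secretion=secretion,
                    receptors=receptors, tissue=tissue, mutations=mutations,
                    q=cfg.get("q", 0.01), h=cfg.get("h", 1.0),
                    cancer_type=cfg.get("cancer_type"),
                    name=cfg.get("name", "tme"))


def save_model(model: TMEModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> TMEModel:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return model_from_dict(cfg, base_dir=path.parent)
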