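"""Assemble the two-column, 16-population network from the configuration.

The network is a directed, pathway-weighted graph over populations named
``<column><layer><class>`` (e.g. ``1L5E``): two cortical columns, four
layers each (L2/3, L4, L5, L6), an excitatory and an inhibitory population
per layer.  Intra-column connection probabilities come from the bundled
table; the only inter-column coupling is L2/3E onto the contralateral
L2/3I.  Structural perturbations (layer-6 silencing, blocking single
L6E->L4 pathways) are expressed by zeroing connection probabilities, never
by deleting populations, so the state-vector shape is constant across
experiments.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .model_core import (
    LAYERS,
    ConfigurationError,
    Pathway,
    PopulationParams,
)

PERTURBATIONS = ("none", "remove_layer6", "block_L6E_to_L4I", "block_L6E_to_L4E")

#: Per-column population labels in canonical order.
POPULATION_ORDER = tuple(
    f"{layer}{cls}" for layer in LAYERS for cls in ("E", "I")
)


def load_default_config() -> dict:
    """Deep copy of the bundled default configuration."""
    with resources.files("colgamma.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def _label(column: int, pop: str) -> str:
    return f"{column}{pop}"


def _parse_label(label: str) -> Tuple[int, str, str]:
    """Split e.g. '2L2/3E' into (column, layer, class)."""
    column = int(label[0])
    layer, cls = label[1:-1], label[-1]
    if column not in (1, 2) or layer not in LAYERS or cls not in ("E", "I"):
        raise ConfigurationError(f"unknown population label {label!r}")
    return column, layer, cls


@dataclass
class NetworkSpec:
    """The populated network: parameters, pathways and perturbation state."""

    populations: List[PopulationParams]
    pathways: List[Pathway]
    P_inter: float
    perturbation: str = "none"
    config: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {p.name: i for i, p in enumerate(self.populations)}
        if len(self._index) != len(self.populations):
            raise ConfigurationError("duplicate population labels")
        for pw in self.pathways:
            if pw.source not in self._index or pw.target not in self._index:
                raise ConfigurationError(
                    f"pathway {pw.source}->{pw.target} references unknown population"
                )

    @property
    def labels(self) -> List[str]:
        return [p.name for p in self.populations]

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise ConfigurationError(f"unknown population label {label!r}") from None

    def population(self, label: str) -> PopulationParams:
        return self.populations[self.index(label)]

    def const_arrays(self) -> Dict[str, np.ndarray]:
        """Per-population constants stacked into arrays (canonical order)."""
        return {
            key: np.array([getattr(p, key) for p in self.populations], dtype=float)
            for key in (
                "zeta", "eta", "kappa", "C",
                "I_back_center", "I_back_width",
                "proj_sensory", "proj_attention",
            )
        }

    def coupling_matrices(self) -> Tuple[np.ndarray, np.ndarray]:
        """Aggregated drive matrices ``A[x, y] = g_peak * P * N_y``.

        ``A_exc`` collects pathways from excitatory sources, ``A_inh`` from
        inhibitory sources; the conductance drive onto population x is then
        ``(A @ r)[x]`` with one aggregated conductance per source class.
        """
        n = self.n_populations
        A_exc = np.zeros((n, n))
        A_inh = np.zeros((n, n))
        for pw in self.pathways:
            src = self.index(pw.source)
            tgt = self.index(pw.target)
            weight = pw.g_peak * pw.P * self.populations[src].N
            if self.populations[src].is_excitatory:
                A_exc[tgt, src] += weight
            else:
                A_inh[tgt, src] += weight
        return A_exc, A_inh

    def to_config(self) -> dict:
        """Configuration dict that rebuilds this spec (round-trip stable)."""
        return copy.deepcopy(self.config)

    def fingerprint(self) -> str:
        """Stable hash of the full structural and parametric content."""
        payload = {
            "populations": [
                {
                    "name": p.name, "cell_class": p.cell_class, "layer": p.layer,
                    "column": p.column, "C": p.C, "g_L": p.g_L, "V_R": p.V_R,
                    "V_T": p.V_T, "N": p.N, "I_back_center": p.I_back_center,
                    "I_back_width": p.I_back_width,
                    "proj_sensory": p.proj_sensory,
                    "proj_attention": p.proj_attention,
                }
                for p in self.populations
            ],
            "pathways": [
                [pw.source, pw.target, pw.P, pw.g_peak] for pw in self.pathways
            ],
            "P_inter": self.P_inter,
            "perturbation": self.perturbation,
        }
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _perturbed_P(source: str, target: str, P: float, perturbation: str) -> float:
    """Apply a structural perturbation by zeroing connection probabilities."""
    if perturbation == "none" or P == 0.0:
        return P
    _, src_layer, src_cls = _parse_label(source)
    tgt_col, tgt_layer, tgt_cls = _parse_label(target)
    src_col = _parse_label(source)[0]
    if perturbation == "remove_layer6":
        if src_layer == "L6" or tgt_layer == "L6":
            return 0.0
    elif perturbation == "block_L6E_to_L4I":
        if src_col == tgt_col and src_layer == "L6" and src_cls == "E" \
                and tgt_layer == "L4" and tgt_cls == "I":
            return 0.0
    elif perturbation == "block_L6E_to_L4E":
        if src_col == tgt_col and src_layer == "L6" and src_cls == "E" \
                and tgt_layer == "L4" and tgt_cls == "E":
            return 0.0
    else:
        raise ConfigurationError(
            f"unknown perturbation {perturbation!r}; valid: {PERTURBATIONS}"
        )
    return P


def build_network(
    config: Optional[dict] = None,
    perturbation: Optional[str] = None,
    delta_E: Optional[float] = None,
    delta_I: Optional[float] = None,
) -> NetworkSpec:
    """Build the validated two-column network.

    Parameters
    ----------
    config : configuration dict (see the bundled default file); ``None``
        loads the default.  Any value may be overridden in the dict.
    perturbation : overrides ``config['perturbation']``.
    delta_E, delta_I : override the background-current half-widths of the
        excitatory / inhibitory populations (the swept heterogeneity pair).
    """
    cfg = copy.deepcopy(config) if config is not None else load_default_config()
    if perturbation is not None:
        cfg["perturbation"] = perturbation
    if delta_E is not None:
        cfg["heterogeneity"]["delta_E"] = float(delta_E)
    if delta_I is not None:
        cfg["heterogeneity"]["delta_I"] = float(delta_I)

    pert = cfg.get("perturbation", "none")
    if pert not in PERTURBATIONS:
        raise ConfigurationError(
            f"unknown perturbation {pert!r}; valid: {PERTURBATIONS}"
        )

    pops_cfg = cfg["populations"]
    het = cfg["heterogeneity"]
    back = cfg["background"]
    proj = cfg["stimulus"]["projection"]
    if het["delta_E"] <= 0 or het["delta_I"] <= 0:
        raise ConfigurationError("heterogeneity half-widths must be positive")

    center_E = float(back["center_E"])
    center_I = center_E * float(back["inhibitory_factor"])

    populations: List[PopulationParams] = []
    for column in (1, 2):
        for pop in POPULATION_ORDER:
            layer, cls = pop[:-1], pop[-1]
            cell_class = "excitatory" if cls == "E" else "inhibitory"
            populations.append(PopulationParams(
                name=_label(column, pop),
                cell_class=cell_class,
                layer=layer,
                column=column,
                C=float(pops_cfg["C"]),
                g_L=float(pops_cfg["g_L"][cell_class]),
                V_R=float(pops_cfg["V_R"]),
                V_T=float(pops_cfg["V_T"]),
                N=int(pops_cfg["counts"][pop]),
                I_back_center=center_E if cls == "E" else center_I,
                I_back_width=float(het["delta_E"] if cls == "E" else het["delta_I"]),
                proj_sensory=float(proj[pop]["sensory"]),
                proj_attention=float(proj[pop]["attention"]),
            ))

    g_peak = cfg["pathways"]["g_peak"]
    P_intra = cfg["pathways"]["P_intra"]
    P_inter = float(cfg["pathways"]["P_inter"])
    if P_inter < 0:
        raise ConfigurationError("P_inter must be non-negative")

    def peak(source_cls: str, target_cls: str) -> float:
        return float(g_peak[source_cls][target_cls])

    pathways: List[Pathway] = []
    # Intra-column pathways: all nonzero table entries, replicated per column.
    for column in (1, 2):
        for tgt_pop in POPULATION_ORDER:
            for src_pop in POPULATION_ORDER:
                P = float(P_intra[tgt_pop][src_pop])
                if P < 0:
                    raise ConfigurationError(
                        f"negative probability for {src_pop}->{tgt_pop}"
                    )
                if P == 0.0:
                    continue
                source = _label(column, src_pop)
                target = _label(column, tgt_pop)
                src_class = "excitatory" if src_pop.endswith("E") else "inhibitory"
                tgt_class = "excitatory" if tgt_pop.endswith("E") else "inhibitory"
                pathways.append(Pathway(
                    source=source,
                    target=target,
                    P=_perturbed_P(source, target, P, pert),
                    g_peak=peak(src_class, tgt_class),
                ))
    # Inter-column pathways: L2/3E -> contralateral L2/3I only.
    for column, other in ((1, 2), (2, 1)):
        pathways.append(Pathway(
            source=_label(column, "L2/3E"),
            target=_label(other, "L2/3I"),
            P=P_inter,
            g_peak=peak("excitatory", "inhibitory"),
        ))

    return NetworkSpec(
        populations=populations,
        pathways=pathways,
        P_inter=P_inter,
        perturbation=pert,
        config=cfg,
    )


def population_counts(spec: NetworkSpec) -> Dict[str, int]:
    """Neuron count per population, keyed by label."""
    return {p.name: p.N for p in spec.populations}
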