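"""A complete demonstration experiment configuration.

The synthetic conditions mirror the functional characterization of the
four cork oak aquaporins expressed in aqy-null yeast: water and glycerol
permeabilities per strain and treatment, mercury activation of QsPIP2;4A
and its beta-mercaptoethanol reversal, activation energies, the
weak-acid intracellular-pH conditions, and a drought-expression stage.
"""

from __future__ import annotations

import copy


_DEMO: dict = {
    "seed": 42,
    "replicates": 10,
    "geometry": {"v0_over_a": 8.33e-5},
    "qc": {"min_r2": 0.9},
    "shock": {
        # sorbitol shock: mild hyperosmotic step, osmol/L
        "water": {"osm_in0": 0.35, "osm_out_inf": 0.42, "noise_sd": 0.005},
        # glycerol shock: external osmolarity doubled entirely by glycerol
        "glycerol": {"osm_in0": 0.35, "osm_out_inf": 0.70, "gly_out": 0.35,
                     "noise_sd": 0.005},
    },
    "strains": [
        {"name": "pUG35",
         "water": {"none": 4.6e-4},
         "glycerol": {"none": 1.55e-8}},
        {"name": "QsPIP2;4A",
         "water": {"none": 6.34e-4, "HgCl2": 9.03e-4, "HgCl2+BME": 7.1e-4}},
        {"name": "QsTIP2;1",
         "water": {"none": 18.7e-4, "HgCl2": 11.0e-4}},
        {"name": "QsNIP1;2",
         "water": {"none": 7.8e-4},
         "glycerol": {"none": 25.84e-8}},
        {"name": "QsNIP6;1",
         "water": {"none": 4.67e-4},
         "glycerol": {"none": 4.38e-8, "HgCl2": 2.28e-8}},
    ],
    "effects": [
        {"strain": "QsPIP2;4A", "kind": "water", "control": "none", "treated": "HgCl2"},
        {"strain": "QsPIP2;4A", "kind": "water", "control": "HgCl2", "treated": "HgCl2+BME"},
        {"strain": "QsTIP2;1", "kind": "water", "control": "none", "treated": "HgCl2"},
        {"strain": "QsNIP6;1", "kind": "glycerol", "control": "none", "treated": "HgCl2"},
    ],
    "arrhenius": [
        {"strain": "pUG35", "kind": "water", "ea": 14.05, "p_ref": 4.6e-4,
         "t_ref_c": 23.0, "temperatures_c": [10, 15, 20, 25, 30, 35]},
        {"strain": "QsTIP2;1", "kind": "water", "ea": 7.3, "p_ref": 18.7e-4,
         "t_ref_c": 23.0, "temperatures_c": [10, 15, 20, 25, 30, 35]},
        {"strain": "QsNIP1;2", "kind": "glycerol", "ea": 6.87, "p_ref": 25.84e-8,
         "t_ref_c": 23.0, "temperatures_c": [10, 15, 20, 25, 30, 35]},
        {"strain": "QsNIP6;1", "kind": "glycerol", "ea": 10.1, "p_ref": 4.38e-8,
         "t_ref_c": 23.0, "temperatures_c": [10, 15, 20, 25, 30, 35]},
    ],
    "weak_acid": [
        {"label": "pH 6.8", "ph_in_true": 6.8, "ph_out": 6.8},
        {"label": "pH 5.0", "ph_in_true": 6.1, "ph_out": 5.0},
        {"label": "pH 5.0 + benzoic acid", "ph_in_true": 4.8, "ph_out": 5.0},
    ],
    "qpcr": [
        {"gene": "QsTIP2;1", "tissue": "young_leaf", "true_log2fc": 1.5,
         "cq_ref": 24.0, "control": "WW", "treated": "WS",
         "n_replicates": 3, "noise_sd": 2.0, "bio_cq_sd": 0.15},
        {"gene": "QsPIP2;4", "tissue": "root", "true_log2fc": -1.2,
         "cq_ref": 25.0, "control": "WW", "treated": "WS",
         "n_replicates": 3, "noise_sd": 2.0, "bio_cq_sd": 0.15},
        {"gene": "QsNIP1;2", "tissue": "young_stem", "true_log2fc": 0.8,
         "cq_ref": 26.0, "control": "WW", "treated": "Rec",
         "n_replicates": 3, "noise_sd": 2.0, "bio_cq_sd": 0.15},
    ],
    "gas_exchange": [
        {"plant_id": "p1", "treatment": "WW", "timepoint": "d10", "A": 9.8, "gs": 118.0, "E": 2.0},
        {"plant_id": "p2", "treatment": "WW", "timepoint": "d10", "A": 10.4, "gs": 131.0, "E": 2.2},
        {"plant_id": "p3", "treatment": "WW", "timepoint": "d10", "A": 9.5, "gs": 122.0, "E": 2.1},
        {"plant_id": "p4", "treatment": "WS", "timepoint": "d10", "A": 7.9, "gs": 78.0, "E": 1.4},
        {"plant_id": "p5", "treatment": "WS", "timepoint": "d10", "A": 8.3, "gs": 84.0, "E": 1.5},
        {"plant_id": "p6", "treatment": "WS", "timepoint": "d10", "A": 7.4, "gs": 73.0, "E": 1.3},
    ],
}


def demo_config_dict() -> dict:
    """A deep copy of the bundled demonstration configuration."""
    return copy.deepcopy(_DEMO)
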