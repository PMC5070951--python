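"""Shared configuration of the demonstration study.

A scaled-down cohort (8 subjects, 6 memory loads, 40 trials per load,
10 parcels at 600 Hz) with planted ground truth: five retention-only
CFS edges across two low frequencies (10 and 13 Hz) and ratios 1:2-1:3,
one load-dependent CFS edge, and one PAC-only edge; moderate linear
mixing between neighbouring parcels; per-subject coupling gain linked
to behavior.  All drivers read and write ``results/demo``.
"""

from crossfreq.pipeline import AnalysisConfig, PipelineConfig
from crossfreq.synth import CouplingSpec, StudyConfig

OUT_DIR = "results/demo"


def demo_truth() -> list[CouplingSpec]:
    # every (parcel, band) slot hosts at most one planted component;
    # 16 Hz carries no planted structure and acts as a null frequency
    return [
        CouplingSpec(0, 1, 10.0, 2, 0.8, "cfs", retention_only=True),
        CouplingSpec(2, 3, 10.0, 2, 0.8, "cfs", retention_only=True),
        CouplingSpec(4, 5, 10.0, 3, 0.8, "cfs", retention_only=True),
        CouplingSpec(8, 0, 10.0, 4, 0.9, "cfs", retention_only=True),
        CouplingSpec(5, 6, 13.0, 2, 0.8, "cfs", retention_only=True),
        CouplingSpec(7, 8, 13.0, 3, 0.8, "cfs", retention_only=True),
        CouplingSpec(1, 2, 10.0, 2, 0.0, "cfs", load_slope=0.15, retention_only=True),
        CouplingSpec(3, 9, 13.0, 3, 0.7, "pac", retention_only=True),
        CouplingSpec(6, 9, 10.0, 1, 0.7, "one_to_one", retention_only=True),
        CouplingSpec(2, 6, 13.0, 1, 0.7, "one_to_one", retention_only=True),
    ]


def demo_config(seed: int = 42, out_dir: str = OUT_DIR) -> PipelineConfig:
    return PipelineConfig(
        out_dir=out_dir,
        study=StudyConfig(
            n_subjects=12,
            n_loads=6,
            n_trials_per_load=60,
            n_parcels=10,
            snr=2.0,
            mixing_width=0.45,
            behavior_coupling_link=2.0,
            seed=seed,
        ),
        truth=demo_truth(),
        analysis=AnalysisConfig(
            f_lows=(10.0, 13.0, 16.0),
            ratios=(2, 3, 4),
            fdr_method="bh",
            consistency_shuffles=2000,
            system_randomizations=5000,
            attribution_permutations=1000,
            snr_sim_samples=100_000,
            snr_top_edges=20,
            seed=seed,
        ),
    )


def parse_args(description: str):
    import argparse

    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=42)
    p.add_argument("--out-dir", default=OUT_DIR)
    return p.parse_args()
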