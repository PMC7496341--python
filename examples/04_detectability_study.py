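"""A reduced end-to-end detectability study from a YAML config.

Writes detectability tables, antler-derived AUC-infinity values per
method, curve plots and a reproducibility manifest into ./results_demo.
The full-size desk study is what scripts/acceptance.py runs; this demo
uses 50 images per class to finish in about a minute.
"""

from pathlib import Path

import yaml

from marbench import run_study

config = {
    "preset": "desk",
    "study": {
        "dose": 8.0e6,
        "amplitude_sweep": [1.03, 1.05],
        "dose_sweep": [8.0e5, 8.0e6],
        "methods": ["fbp", "mar2"],
        "n_images_per_class": 50,
        "nt_values": [25, 30, 40],
        "repetitions": 10,
        "master_seed": 0,
    },
}
cfg_path = Path("results_demo_config.yaml")
cfg_path.write_text(yaml.safe_dump(config))
out = run_study(cfg_path, "results_demo")
print(f"\nwrote {sorted(p.name for p in out.iterdir())}")
print((out / "detectability_amplitude.csv").read_text())
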