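#!/usr/bin/env python
"""Run the full recognition protocol on user-downloaded BCI competition recordings.

The Graz BCI competition datasets (IV-IIb: 9 subjects, 2 classes, 3 channels,
250 Hz; III-IIIa: 3 subjects, 4 classes, 60 channels, 250 Hz) are not
redistributable and must be downloaded by the user from
http://www.bbci.de/competition/iv/ and http://www.bbci.de/competition/iii/.
Given one or more subject files this script runs the standard configuration
(0.5-30 Hz band-pass, contribution-rate channel split, LCD + CSP serial
fusion, sigmoid ELM, 5x5-fold cross-validation) and prints per-subject and
average accuracy and kappa next to the published reference averages for
context (IIb fused-feature ELM: 0.7832; IIIa: 0.8347). This is a convenience
script for qualitative comparison, not a test: the published numbers depend
on unstated preprocessing windows and hyperparameters.

Example:
    python scripts/competition_protocol.py --dialect gdf \\
        --class-code 769 1 --class-code 770 2 B0101T.gdf B0201T.gdf
"""

from __future__ import annotations

import argparse

import numpy as np

from mielm import MotorImageryELM, PipelineConfig, extract_epochs, load_recording

REFERENCE = {2: 0.7832, 4: 0.8347}  # published fused-feature ELM averages


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("files", nargs="+", help="subject recordings")
    parser.add_argument("--dialect", choices=["gdf", "mat"], required=True)
    parser.add_argument(
        "--class-code", nargs=2, type=int, action="append", required=True,
        metavar=("EVENT", "CLASS"), help="event-code -> class-id mapping"
    )
    parser.add_argument("--window-start", type=float, default=0.5)
    parser.add_argument("--window-len", type=float, default=3.0)
    parser.add_argument("--n-hidden", type=int, default=40)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    codes = {event: cls for event, cls in args.class_code}
    config = PipelineConfig(
        window_start_s=args.window_start,
        window_len_s=args.window_len,
        n_hidden=args.n_hidden,
        seed=args.seed,
    )
    accs, kappas = [], []
    for path in args.files:
        rec = load_recording(path, args.dialect)
        epochs = extract_epochs(
            rec, codes, window_start_s=config.window_start_s,
            window_len_s=config.window_len_s,
        )
        cv = MotorImageryELM(epochs, config).cross_validate(seed=args.seed)
        accs.append(cv.mean_acc)
        kappas.append(cv.mean_kappa)
        print(f"{path}: A_bar = {cv.mean_acc:.4f}  K_bar = {cv.mean_kappa:.4f}")
    n_classes = len(set(codes.values()))
    ref = REFERENCE.get(n_classes)
    print(f"\naverage over {len(accs)} subject(s): "
          f"A_bar = {np.mean(accs):.4f}  K_bar = {np.mean(kappas):.4f}")
    if ref is not None:
        print(f"published fused-feature ELM average for comparison: {ref}")


if __name__ == "__main__":
    main()
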