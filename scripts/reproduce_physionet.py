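#!/usr/bin/env python
"""Optional reproduction of the real-record NSR/CHF classification.

Requires network access and the optional ``wfdb`` package (``pip install
wfdb``) — it downloads the MIT-BIH Normal Sinus Rhythm database (nsrdb,
128 Hz) and the BIDMC Congestive Heart Failure database (chfdb, 250 Hz)
from PhysioNet, cuts 64-s segments, denoises them ('bior2.6', 8 levels),
extracts the (MSEN1, MSEN2, alpha_0, alpha_min) features and evaluates the
stratified 5-fold ELM (60 hidden nodes).

This script is deliberately NOT exercised by the test suite or the
acceptance script: the published headline accuracies are reproducible only
against the downloaded records.

Usage:
    python scripts/reproduce_physionet.py --data-dir scratch/physionet \
        --segments-per-class 360 --seed 0
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from mfecg import SegmentFeaturizer, denoise, run_pipeline
from mfecg.io import ECGRecord, segment

NSR_RECORDS = ["16265", "16272", "16273", "16420", "16483", "16539",
               "16773", "16786", "16795", "17052", "17453", "18177",
               "18184", "19088", "19090", "19093", "19140", "19830"]
CHF_RECORDS = [f"chf{i:02d}" for i in range(1, 16)]


def fetch_records(data_dir: Path):
    try:
        import wfdb
    except ImportError as exc:
        raise SystemExit("this script needs the optional 'wfdb' package "
                         "(pip install wfdb) and network access") from exc
    records = []
    for db, names, label in (("nsrdb", NSR_RECORDS, "NSR"),
                             ("chfdb", CHF_RECORDS, "CHF")):
        for name in names:
            local = data_dir / db / name
            if not (local.with_suffix(".hea")).exists():
                wfdb.dl_database(db, dl_dir=str(data_dir / db),
                                 records=[name])
            rec = wfdb.rdrecord(str(local))
            for channel in range(rec.n_sig):
                records.append(ECGRecord(
                    samples=np.asarray(rec.p_signal[:, channel], float),
                    fs=float(rec.fs), label=label, record_id=name,
                    channel=channel))
    return records


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path,
                        default=Path("scratch/physionet"))
    parser.add_argument("--segments-per-class", type=int, default=360)
    parser.add_argument("--nsr-extra", type=int, default=180,
                        help="extra NSR segments for the unbalanced set")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    records = fetch_records(args.data_dir)
    per_class = {"NSR": args.segments_per_class + args.nsr_extra,
                 "CHF": args.segments_per_class}
    segs, labels = [], []
    counts = {"NSR": 0, "CHF": 0}
    for rec in records:
        for seg in segment(rec, 64.0):
            if counts[rec.label] >= per_class[rec.label]:
                break
            segs.append(denoise(seg).samples)
            labels.append(rec.label)
            counts[rec.label] += 1
    print(f"using {counts['NSR']} NSR and {counts['CHF']} CHF segments")

    X = SegmentFeaturizer().transform(segs)
    rep = run_pipeline(X, np.array(labels), K=5, n_hidden=60, seed=args.seed)
    doc = {"pooled_confusion": vars(rep.pooled), "metrics": rep.metrics,
           "fold_accuracy": rep.fold_accuracy, "n_dropped": rep.n_dropped}
    text = json.dumps(doc, indent=2)
    print(text)
    if args.out:
        args.out.write_text(text)


if __name__ == "__main__":
    main()
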