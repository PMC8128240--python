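"""Summarize classifier resilience under cumulative test-data degradation.

Reads the full-gene-set summary produced by 03_classify_full.py and reports
the per-method AUC/PCC decay across the three degradation levels and the
native-to-level-1 drop ordering (the resilience headline).
"""

from pathlib import Path

import pandas as pd

RESULTS = Path("results")
LEVELS = ["native", "level1", "level2", "level3"]


def main() -> None:
    summary = pd.read_csv(RESULTS / "performance_full.csv")
    rows = []
    for metric in ("auc", "pcc"):
        t = summary.pivot_table(index="method", columns="level", values=f"{metric}_mean")[LEVELS]
        for method in t.index:
            seq = t.loc[method]
            rows.append(
                {
                    "metric": metric.upper(),
                    "method": method,
                    **{lv: round(seq[lv], 4) for lv in LEVELS},
                    "native_to_level1_drop": round(seq["native"] - seq["level1"], 4),
                }
            )
    report = pd.DataFrame(rows)
    report.to_csv(RESULTS / "resilience_summary.csv", index=False)

    auc = report[report["metric"] == "AUC"].set_index("method")
    order = auc["native_to_level1_drop"].sort_values()
    print("Native-to-level-1 AUC drop per method (smallest = most resilient):")
    print(order.to_string())
    most = order.index[0]
    print(f"\nMost noise-resilient method: {most}")
    print("Report written to results/resilience_summary.csv")


if __name__ == "__main__":
    main()
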