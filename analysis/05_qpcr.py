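"""Relative gene expression by the comparative threshold cycle method.

Reads results/data/qpcr_ct.csv, computes per-sample dCt/ddCt/fold with 18S
normalization, tests disuse vs control on ddCt values per gene, and writes
results/ddct.csv and results/ddct_tests.csv.
"""
import pandas as pd

from osteoflow import io
from osteoflow.stats import ddct, ddct_condition_tests

if __name__ == "__main__":
    ct = pd.read_csv("results/data/qpcr_ct.csv")
    table = ddct(ct, housekeeping="18S", reference="control")
    tests = ddct_condition_tests(table)
    io.write_table(table, "results/ddct.csv")
    io.write_table(tests, "results/ddct_tests.csv")
    print(tests.round(4).to_string(index=False))
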