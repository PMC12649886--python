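"""Quantify membrane wounding: percent dextran-retaining cells per field,
compared between conditions.

Reads the TIFF fields under results/data/images/, writes
results/pmd_fields.csv and results/pmd_comparison.csv.
"""
from pathlib import Path

from osteoflow import io
from osteoflow.pipeline import pmd_compare
from osteoflow.pmd import count_pmd_field, fields_to_frame

if __name__ == "__main__":
    fields = []
    for path in sorted(Path("results/data/images").glob("*.tif")):
        stack = io.read_image_stack(path)
        condition = path.stem.rsplit("_", 1)[0]
        fields.append(count_pmd_field(stack[0], stack[1], field_id=path.stem,
                                      condition=condition))
    fields_df = fields_to_frame(fields)
    io.write_table(fields_df, "results/pmd_fields.csv")
    comparison = pmd_compare(fields_df)
    io.write_table(comparison, "results/pmd_comparison.csv")
    print(fields_df.round(2).to_string(index=False))
    print(comparison.round(4).to_string(index=False))
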