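"""Glycan co-occurrence networks per venom (pairs sharing >= 3 sites).

Exports the edge and node tables and summarizes network size per venom;
group-structured repertoires should give each venom group a recognizably
different network.
"""

from _common import get_bundle, get_records, outpath
from venomglyco.network import cooccurrence, edge_table, node_table


def main():
    bundle = get_bundle()
    records = get_records(bundle)
    edges = cooccurrence(records, min_weight=3)

    et = edge_table(edges)
    et.to_csv(outpath("06_cooccurrence_edges.tsv"), sep="\t", index=False)
    nt = node_table(edges)
    nt.to_csv(outpath("06_cooccurrence_nodes.tsv"), sep="\t", index=False)

    summary = (
        et.groupby("sample_id")
        .agg(n_edges=("weight", "size"), max_weight=("weight", "max"))
        .join(nt.groupby("sample_id").size().rename("n_nodes"))
        .reset_index()
    )
    print(summary.to_string(index=False))
    if len(et):
        top = et.sort_values("weight", ascending=False).iloc[0]
        print(f"strongest co-occurring pair ({top['sample_id']}, weight "
              f"{top['weight']}): {top['comp_a']}  <->  {top['comp_b']}")


if __name__ == "__main__":
    main()
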