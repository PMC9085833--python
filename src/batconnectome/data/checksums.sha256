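2beba67ebdf634e7536058d12a1ec865c6b160044ef2ceb5e97e1fdeab46003b  known_bat_genes.txt
2732371f5a7bf3348c934860a9c9105bca959d1bfd6de76af4a08f4351d3b8f7  bat_candidate_genes.tsv
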