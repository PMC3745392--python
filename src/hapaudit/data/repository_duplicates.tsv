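# Duplicate groups among the 40 repository haplotype entries: repository
# haplotype ids (ordinal 1-40) and their accession numbers.  Entries not
# listed here are singletons.
group	haplotype_ids	accessions
1	31, 32, 37, 40	AM287245, AM287246, AM287251, AM287254
2	19, 21, 29	AM287233, AM287235, AM287243
3	5, 28	AM287219, AM287242
4	16, 25	AM287230, AM287239
5	11, 17	AM287225, AM287231
6	7, 9	AM287221, AM287223
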