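variant_id	kind	decision	lof_class	evidence
mid_stop	plof		LoF	truncation subject to NMD (67% of CDS lost)
last_exon_10pct	plof		not_LoF	NMD-escape region (last exon / final 50 bp of penultimate), truncates only 10% of CDS: not LoF
penult_tail_30pct	plof		LoF	NMD-escape region but truncates 30% of CDS (> 25%): override, kept LoF
splice_rescue_4bp	plof		likely_not_LoF	in-frame alternative splice site 4 bp away: essential rescue
splice_possible_10bp	plof		uncertain	possible in-frame rescue 10 bp away, not validated: uncertain
splice_validated_10bp	plof		likely_not_LoF	in-frame alternative site 10 bp away, externally validated rescue
low_pext_stop	plof		likely_LoF	truncation subject to NMD (67% of CDS lost) | pext 0.02 below 0.10: downgraded one class
gnomad_flagged_stop	plof		likely_LoF	flagged by gnomAD variant QC: downgraded one class | truncation subject to NMD (67% of CDS lost)
blacklisted	plof		not_LoF	site on genotyping-quality blacklist
loftee_lc	plof		not_LoF	LOFTEE annotation not high-confidence
cv_accept	clinvar	clinically_significant		adjusted_af 1.6e-05 within cut-off 0.0001 | P/LP from registry lab(s) BigLab since 2017-01-01
cv_predates	clinvar	manual_review		adjusted_af 1.6e-05 within cut-off 0.0001 | no qualifying registry submission
cv_benign	clinvar	excluded		adjusted_af 1.6e-05 within cut-off 0.0001 | B/LB from registry lab(s) BigLab since 2017-01-01
cv_conflict	clinvar	manual_review		adjusted_af 1.6e-05 within cut-off 0.0001 | conflicting registry assertions (P/LP vs B/LB)
cv_nonregistry	clinvar	manual_review		adjusted_af 1.6e-05 within cut-off 0.0001 | no qualifying registry submission
cv_highfreq	clinvar	excluded		adjusted_af 0.02 exceeds condition cut-off 0.0001
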