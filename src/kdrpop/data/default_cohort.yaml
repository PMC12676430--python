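# Default synthetic cohort: eight collection sites across the three
# ecological zones of Burkina Faso, with the kdr haplotype-class structure the
# analysis expects: An. gambiae s.s. essentially fixed for FVI; An. coluzzii
# segregating for LVI / FVI / LL1T / FL1T with the g>c classes (LL2T, FL2T)
# rare and absent from Nassan and Po-Dongo; An. arabiensis mixing FVI and SVI.
# Gene coordinates below are illustrative placeholders (synthetic), not
# genome-build coordinates; ids and families are the real detoxification
# gene families (COE / GST / CYP) plus Ace1.
region: {contig: 2L, start: 2358158, end: 2431617}
n_private_mutations: 2

genes:
  - {gene_id: AGAP002863, gene_name: COEAE60, family: COE, contig: 2R, start: 28548000, end: 28551000}
  - {gene_id: AGAP005835, gene_name: COEJHE3E, family: COE, contig: 2L, start: 37280000, end: 37283000}
  - {gene_id: AGAP009194, gene_name: GSTE2, family: GST, contig: 3R, start: 28597000, end: 28598500}
  - {gene_id: AGAP004173, gene_name: GSTD5, family: GST, contig: 2L, start: 640000, end: 641500}
  - {gene_id: AGAP000818, gene_name: CYP9K1, family: CYP, contig: X, start: 15240000, end: 15243000}
  - {gene_id: AGAP002862, gene_name: CYP6AA1, family: CYP, contig: 2R, start: 28491000, end: 28493000}
  - {gene_id: AGAP008212, gene_name: CYP6M2, family: CYP, contig: 3R, start: 6928000, end: 6930500}
  - {gene_id: AGAP012296, gene_name: CYP12F2, family: CYP, contig: 2R, start: 56000000, end: 56002000}
  - {gene_id: AGAP001356, gene_name: ACE1, family: other, contig: 2R, start: 3483099, end: 3497400}

populations:
  # --- An. coluzzii, the species carrying the 402/1527 double-mutant classes
  - name: Bana_Acol
    species: An_coluzzii
    site: Bana
    zone: Sudanian
    n_samples: 60
    n_background_sites: 500
    kdr_hap_freqs: {LVI: 0.25, FVI: 0.225, LL1T: 0.30, FL1T: 0.175, LL2T: 0.03, FL2T: 0.02}
    cn_specs:
      AGAP002863: {amp_freq: 0.85}
      AGAP000818: {amp_freq: 0.71}
      AGAP004173: {del_freq: 0.60}
      AGAP002862: {amp_freq: 0.40}
  - name: Souroukoudinga_Acol
    species: An_coluzzii
    site: Souroukoudinga
    zone: Sudanian
    n_samples: 60
    n_background_sites: 500
    kdr_hap_freqs: {LVI: 0.28, FVI: 0.195, LL1T: 0.28, FL1T: 0.195, LL2T: 0.03, FL2T: 0.02}
    cn_specs:
      AGAP002863: {amp_freq: 0.73}
      AGAP000818: {amp_freq: 0.42}
      AGAP004173: {del_freq: 0.70}
  - name: Sideradougou_Acol
    species: An_coluzzii
    site: Sideradougou
    zone: Sudanian
    n_samples: 60
    n_background_sites: 500
    kdr_hap_freqs: {LVI: 0.22, FVI: 0.25, LL1T: 0.32, FL1T: 0.16, LL2T: 0.03, FL2T: 0.02}
    cn_specs:
      AGAP002863: {amp_freq: 0.30}
      AGAP004173: {del_freq: 0.55}
      AGAP001356: {amp_freq: 0.15}
  - name: PoDongo_Acol
    species: An_coluzzii
    site: Po-Dongo
    zone: Sudanian
    n_samples: 60
    n_background_sites: 500
    kdr_hap_freqs: {LVI: 0.27, FVI: 0.25, LL1T: 0.30, FL1T: 0.18}
    cn_specs:
      AGAP002863: {amp_freq: 0.25}
      AGAP004173: {del_freq: 0.53}
  - name: Nagare_Acol
    species: An_coluzzii
    site: Nagare
    zone: Sudano_Sahelian
    n_samples: 60
    n_background_sites: 500
    kdr_hap_freqs: {LVI: 0.26, FVI: 0.21, LL1T: 0.31, FL1T: 0.17, LL2T: 0.03, FL2T: 0.02}
    cn_specs:
      AGAP002863: {amp_freq: 0.26}
      AGAP001356: {amp_freq: 0.12}
  - name: Gama_Acol
    species: An_coluzzii
    site: Gama
    zone: Sudano_Sahelian
    n_samples: 60
    n_background_sites: 500
    kdr_hap_freqs: {LVI: 0.24, FVI: 0.23, LL1T: 0.30, FL1T: 0.18, LL2T: 0.03, FL2T: 0.02}
    cn_specs:
      AGAP008212: {amp_freq: 0.20}
      AGAP001356: {amp_freq: 0.10}
  - name: Nassan_Acol
    species: An_coluzzii
    site: Nassan
    zone: Sudano_Sahelian
    n_samples: 60
    n_background_sites: 500
    kdr_hap_freqs: {LVI: 0.26, FVI: 0.24, LL1T: 0.31, FL1T: 0.19}
    cn_specs:
      AGAP002863: {amp_freq: 0.64}
      AGAP012296: {del_freq: 0.40}
  - name: OuroHesso_Acol
    species: An_coluzzii
    site: Ouro-Hesso
    zone: Sahelian
    n_samples: 60
    n_background_sites: 500
    kdr_hap_freqs: {LVI: 0.23, FVI: 0.22, LL1T: 0.33, FL1T: 0.17, LL2T: 0.03, FL2T: 0.02}
    cn_specs:
      AGAP000818: {amp_freq: 0.20}

  # --- An. gambiae s.s.: essentially fixed for the FVI background
  - name: Bana_Agam
    species: An_gambiae_ss
    site: Bana
    zone: Sudanian
    n_samples: 30
    n_background_sites: 300
    kdr_hap_freqs: {FVI: 0.995, LVI: 0.005}
    cn_specs:
      AGAP000818: {amp_freq: 0.90}
      AGAP004173: {del_freq: 1.0}
  - name: PoDongo_Agam
    species: An_gambiae_ss
    site: Po-Dongo
    zone: Sudanian
    n_samples: 30
    n_background_sites: 300
    kdr_hap_freqs: {FVI: 0.995, LVI: 0.005}
    cn_specs:
      AGAP004173: {del_freq: 1.0}
  - name: Gama_Agam
    species: An_gambiae_ss
    site: Gama
    zone: Sudano_Sahelian
    n_samples: 30
    n_background_sites: 300
    kdr_hap_freqs: {FVI: 0.995, LVI: 0.005}
    cn_specs:
      AGAP000818: {amp_freq: 0.85}
      AGAP001356: {amp_freq: 0.20}
  - name: Sideradougou_Agam
    species: An_gambiae_ss
    site: Sideradougou
    zone: Sudanian
    n_samples: 30
    n_background_sites: 300
    kdr_hap_freqs: {FVI: 0.995, LVI: 0.005}
    cn_specs:
      AGAP004173: {del_freq: 1.0}
      AGAP001356: {amp_freq: 0.25}

  # --- An. arabiensis: FVI and SVI co-occurring, no 402/1527 mutants
  - name: Nassan_Aara
    species: An_arabiensis
    site: Nassan
    zone: Sudano_Sahelian
    n_samples: 40
    n_background_sites: 400
    kdr_hap_freqs: {FVI: 0.45, SVI: 0.30, LVI: 0.25}
    cn_specs:
      AGAP005835: {amp_freq: 0.64}
      AGAP012296: {del_freq: 0.68}
      AGAP004173: {del_freq: 1.0}
  - name: PoDongo_Aara
    species: An_arabiensis
    site: Po-Dongo
    zone: Sudanian
    n_samples: 40
    n_background_sites: 400
    kdr_hap_freqs: {FVI: 0.50, SVI: 0.36, LVI: 0.14}
    cn_specs:
      AGAP005835: {amp_freq: 0.50}
      AGAP012296: {del_freq: 0.90}
      AGAP004173: {del_freq: 1.0}
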