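# Parkinson-style reference restraint values -- SYNTHETIC stand-in, v1.
# The 1996 standard nucleic-acid compilation keys sugar bond/angle targets only by sugar
# type (ribose vs 2'-deoxyribose; glycosidic-link parameters by base type), with no pucker,
# chi or gamma conditioning and no functional forms. This file is a synthetic stand-in
# constructed from widely reproduced values of that style for use as the comparison
# baseline; it is NOT a transcription of the published reference columns.
# Schema identical to sugar_targets_synthetic.csv.
parameter,kind,sugar,base,pucker,chi,gamma,terminal,form,value,a,b,c,sigma,n
C1'-C2',bond,ribose,*,*,*,*,*,fixed,1.529,,,,0.011,80
C1'-C2',bond,deoxyribose,*,*,*,*,*,fixed,1.519,,,,0.010,47
C2'-C3',bond,ribose,*,*,*,*,*,fixed,1.523,,,,0.011,80
C2'-C3',bond,deoxyribose,*,*,*,*,*,fixed,1.516,,,,0.011,47
C3'-C4',bond,ribose,*,*,*,*,*,fixed,1.521,,,,0.010,80
C3'-C4',bond,deoxyribose,*,*,*,*,*,fixed,1.528,,,,0.010,47
C4'-O4',bond,ribose,*,*,*,*,*,fixed,1.453,,,,0.008,80
C4'-O4',bond,deoxyribose,*,*,*,*,*,fixed,1.446,,,,0.010,47
O4'-C1',bond,ribose,*,*,*,*,*,fixed,1.414,,,,0.012,80
O4'-C1',bond,deoxyribose,*,*,*,*,*,fixed,1.420,,,,0.011,47
C2'-O2',bond,ribose,*,*,*,*,*,fixed,1.420,,,,0.010,80
C4'-C5',bond,ribose,*,*,*,*,*,fixed,1.508,,,,0.007,80
C4'-C5',bond,deoxyribose,*,*,*,*,*,fixed,1.511,,,,0.008,47
C1'-N,bond,*,purine,*,*,*,*,fixed,1.459,,,,0.010,58
C1'-N,bond,*,pyrimidine,*,*,*,*,fixed,1.471,,,,0.012,69
C3'-O3',bond,ribose,*,*,*,*,*,fixed,1.423,,,,0.014,80
C3'-O3',bond,deoxyribose,*,*,*,*,*,fixed,1.431,,,,0.013,47
C5'-O5',bond,ribose,*,*,*,*,*,fixed,1.440,,,,0.016,80
C5'-O5',bond,deoxyribose,*,*,*,*,*,fixed,1.443,,,,0.016,47
C1'-C2'-C3',angle,ribose,*,*,*,*,*,fixed,101.5,,,,1.2,80
C1'-C2'-C3',angle,deoxyribose,*,*,*,*,*,fixed,102.0,,,,1.2,47
C2'-C3'-C4',angle,ribose,*,*,*,*,*,fixed,102.6,,,,1.2,80
C2'-C3'-C4',angle,deoxyribose,*,*,*,*,*,fixed,103.1,,,,1.2,47
C3'-C4'-O4',angle,ribose,*,*,*,*,*,fixed,104.0,,,,1.2,80
C3'-C4'-O4',angle,deoxyribose,*,*,*,*,*,fixed,105.6,,,,1.2,47
C4'-O4'-C1',angle,ribose,*,*,*,*,*,fixed,109.6,,,,1.1,80
C4'-O4'-C1',angle,deoxyribose,*,*,*,*,*,fixed,110.0,,,,1.1,47
O4'-C1'-C2',angle,ribose,*,*,*,*,*,fixed,106.4,,,,1.1,80
O4'-C1'-C2',angle,deoxyribose,*,*,*,*,*,fixed,106.1,,,,1.1,47
C1'-C2'-O2',angle,ribose,*,*,*,*,*,fixed,110.6,,,,1.4,80
C3'-C2'-O2',angle,ribose,*,*,*,*,*,fixed,113.3,,,,1.5,80
C2'-C3'-O3',angle,ribose,*,*,*,*,*,fixed,111.0,,,,1.6,80
C2'-C3'-O3',angle,deoxyribose,*,*,*,*,*,fixed,110.3,,,,1.6,47
C4'-C3'-O3',angle,ribose,*,*,*,*,*,fixed,110.3,,,,1.6,80
C4'-C3'-O3',angle,deoxyribose,*,*,*,*,*,fixed,110.8,,,,1.6,47
C3'-C4'-C5',angle,ribose,*,*,*,*,*,fixed,115.5,,,,1.5,80
C3'-C4'-C5',angle,deoxyribose,*,*,*,*,*,fixed,114.7,,,,1.5,47
C5'-C4'-O4',angle,ribose,*,*,*,*,*,fixed,109.2,,,,1.4,80
C5'-C4'-O4',angle,deoxyribose,*,*,*,*,*,fixed,109.4,,,,1.4,47
C4'-C5'-O5',angle,ribose,*,*,*,*,*,fixed,111.7,,,,1.9,80
C4'-C5'-O5',angle,deoxyribose,*,*,*,*,*,fixed,111.0,,,,1.9,47
N-C1'-C2',angle,*,purine,*,*,*,*,fixed,113.4,,,,1.6,58
N-C1'-C2',angle,*,pyrimidine,*,*,*,*,fixed,112.7,,,,1.6,69
N-C1'-O4',angle,*,purine,*,*,*,*,fixed,108.3,,,,1.4,58
N-C1'-O4',angle,*,pyrimidine,*,*,*,*,fixed,108.2,,,,1.4,69
C1'-N-C2/C4,angle,*,purine,*,*,*,*,fixed,126.3,,,,1.5,58
C1'-N-C2/C4,angle,*,pyrimidine,*,*,*,*,fixed,117.7,,,,1.5,69
C1'-N-C6/C8,angle,*,purine,*,*,*,*,fixed,127.1,,,,1.5,58
C1'-N-C6/C8,angle,*,pyrimidine,*,*,*,*,fixed,121.2,,,,1.5,69
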