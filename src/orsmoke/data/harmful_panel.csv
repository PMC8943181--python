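name,cas,formula,mw_g_mol,hazards,limit_osha_ppb,limit_niosh_ppb,limit_suspect,avg_ppb_paper,max_ppb_paper
Hydrogen cyanide,74-90-8,CHN,27.03,acute_toxic,4700,,false,0.58,22.71
Formaldehyde,50-00-0,CH2O,30.03,carcinogenic;mutagenic;acute_toxic;corrosive,750,16,false,9.12,1721.95
Methanol,67-56-1,CH4O,32.04,acute_toxic,4200,,true,5.06,287.34
Acetonitrile,75-05-8,C2H3N,41.05,acute_toxic;irritant;odor,40000,20000,false,1.11,55.38
Acetaldehyde,75-07-0,C2H4O,44.05,carcinogenic;mutagenic;irritant;odor,25000,,false,141.6,1739.66
Formic acid,64-18-6,CH2O2,46.03,acute_toxic;corrosive;odor,5000,,false,0.15,19.35
Ethanol,64-17-5,C2H6O,46.07,irritant;odor,1000000,,true,34.84,2054.08
Methanethiol,74-93-1,CH4S,48.11,acute_toxic;odor,500,,false,0.01,7.56
Acrylonitrile,107-13-1,C3H3N,53.06,carcinogenic;acute_toxic;irritant;corrosive;odor,2000,1000,false,0.02,14.57
"1,3-butadiene/1-Butyne",106-99-0;107-00-6,C4H6,54.09,carcinogenic;mutagenic;odor,1000,,false,16.89,1066.49
Propionitrile,107-12-0,C3H5N,55.08,acute_toxic;irritant;odor,6000,,false,0.03,13.63
Butenes,106-98-9;624-64-6;590-18-1;115-11-7,C4H8,56.11,irritant;odor,,,false,5.22,128.66
Acetone/Propanal,67-64-1;123-38-6,C3H6O,58.08,irritant;odor,1000000,,false,42.17,521.66
3-butenenitrile/pyrrole,109-75-1;109-97-7,C4H5N,67.09,acute_toxic;odor;mutagenic,,,false,0.02,20.49
"1,3-pentadiene",2004-70-8,C5H8,68.12,odor;carcinogenic,,,false,3.25,196.38
Crotonaldehyde,123-73-9,C4H6O,70.09,acute_toxic;irritant;corrosive;odor,2000,,false,0.39,12.05
Benzene,71-43-2,C6H6,78.11,carcinogenic;mutagenic;irritant;odor,1000,100,false,0.31,35.14
Pyridine,110-86-1,C5H5N,79.10,acute_toxic;irritant;odor,5000,,false,0.02,2.61
2-Methylbutanenitrile/Isovaleronitrile,18936-17-9;625-28-5,C5H9N,83.13,acute_toxic;irritant;odor,,,false,0.02,5.30
3-Methyl-2-butenal,107-86-8,C5H8O,84.12,acute_toxic;irritant;corrosive;odor,,,false,0.11,2.96
gamma-Butyrolactone,96-48-0,C4H6O2,86.09,acute_toxic;irritant;corrosive,50000,,false,0.62,4.34
Isovaleraldehyde/2-Methylbutyraldehyde/Pentanal,590-86-3;96-17-3;110-62-3,C5H10O,86.13,acute_toxic;irritant;odor,,,false,0.62,128.95
Toluene,108-88-3,C7H8,92.14,teratogenic;irritant;odor,200000,,false,0.49,123.60
Phenol,108-95-2,C6H6O,94.11,mutagenic;acute_toxic;corrosive;odor,5000,,false,2.84,10.44
Furfural,98-01-1,C5H4O2,96.08,carcinogenic;acute_toxic;odor,2000,,false,0.07,3.07
"2,5-dimethylfuran",625-86-5,C6H8O,96.13,irritant;odor,,,false,0.07,1.74
Methyl methacrylate,80-62-6,C5H8O2,100.12,irritant;odor,100000,,false,0.33,2.13
Styrene,100-42-5,C8H8,104.15,teratogenic;carcinogenic;irritant;odor,100000,,false,0.13,2.51
"2,3-Dihydroindene (Indane)/3-Methylstyrene",496-11-7;100-80-1,C9H10,118.18,irritant;odor,,,false,0.09,1.48
n-Propylbenzene (Pseudocumene),103-65-1,C9H12,120.19,irritant;odor,,,false,0.15,24.97
Desflurane,57041-67-5,C3H2F6O,168.04,irritant;odor,,,false,1.46,1002.03
Sevoflurane,28523-86-6,C4H3F7O,200.05,irritant;odor,,,false,4.91,757.78
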