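id,age,sex,gene,mutation1,mutation2,photophobia,nystagmus,color_vision,bcva_od,bcva_os,se_od,se_os,oct_stage,foveal_hypoplasia,swaf_ring,niraf_hypo,ise_width_deg,study_eye
1,39,F,CNGA3,c.1306C>T (p.Arg436Trp),c.1320delG (p.Trp440Cysfs*25),1,0,severe,20/200,20/200,-5.25,-4,3,0,0,present,,OD
2,19,F,CNGA3,c.464delA (p.Lys155Argfs*18),c.464delA (p.Lys155Argfs*18),1,1,severe,20/140,20/200,-5.5,-5.75,1,0,0,absent,0,OD
3,35,M,CNGA3,c.667C>T (p.Arg223Trp),c.667C>T (p.Arg223Trp),1,1,severe,20/500,20/250,0.5,2,4,0,1,present,,OD
4,10,M,CNGA3,c.847C>T (p.Arg283Trp),c.1495C>T (p.Arg499*),1,1,severe,20/200,20/160,5.25,5.5,1,0,1,absent,0,OD
5,33,F,CNGA3,c.542A>G (p.Tyr181Cys),c.542A>G (p.Tyr181Cys),1,0,partial,20/100,20/100,-6.5,-6.75,3,1,0,borderline,,OD
6,18,F,CNGA3,c.1641C>A (p.Phe547Leu),c.1641C>A (p.Phe547Leu),1,1,severe,20/200,20/200,1.25,1.25,4,1,1,present,,OD
7,40,M,CNGA3,c.661C>T (p.Arg221*),c.1279C>T (p.Arg427Cys),0,1,severe,20/400,20/200,0.25,0.25,2,1,1,borderline,,OD
8,10,F,CNGA3,c.1669G>A (p.Gly557Arg),c.1669G>A (p.Gly557Arg),0,1,partial,20/80,20/100,-2.25,-3.75,3,1,1,absent,,OD
9,12,F,CNGB3,c.1148delC (p.Thr383Ilefs*13),c.1148delC (p.Thr383Ilefs*13),1,1,partial,20/200,20/200,0.25,-0.25,2,0,1,absent,,OD
10,44,F,CNGB3,c.1006G>T (p.Glu336*),c.1006G>T (p.Glu336*),0,0,partial,20/125,20/160,-5.75,-5.75,4,1,1,present,,OD
11,29,F,CNGB3,c.819_826del (p.Arg274Valfs*13),c.1243C>T (p.Gln415*),1,0,severe,20/200,20/200,-6.75,-5.25,1,1,1,absent,0,OD
12,14,M,CNGB3,c.130-1G>T (p.?),c.130-1G>T (p.?),1,1,severe,20/100,20/125,-0.25,-1.25,2,1,0,absent,,OD
13,21,F,CNGB3,c.129+2T>C (p.?),Deletion of exon 3 (p.?),1,1,partial,20/200,20/125,-0.5,-0.5,2,0,1,present,,OD
14,32,F,CNGB3,c.3G>A (p.Met1?),c.1148delC (p.Thr383Ilefs*13),0,1,severe,20/160,20/160,-2.25,-2.25,2,1,1,present,,OD
15,15,F,CNGB3,c.129+2T>C (p.?),Deletion of exon 3 (p.?),1,0,severe,20/130,20/130,-1,-1.25,1,0,1,absent,0,OD
16,31,M,PDE6C,c.857del (p.Lys286fs*16),c.857del (p.Lys286fs*16),1,0,unknown,20/100,20/100,2,2.25,4,0,1,present,,OD
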