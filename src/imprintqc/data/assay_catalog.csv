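name,chromosome,position,parental_mark,timing,avg_somatic_methylation,location_category,cpg_island,ctcf_class,cpg_density,cluster_id
DIRAS3 (3),1,68285444,Maternal,Somatic,70.22,gene_body_exonic,Yes,YV,6.2,DIRAS3
DIRAS3 (2),1,68288969,Maternal,Germ-line#,50.42,promoter,Yes,N,5.6,DIRAS3
DIRAS3 (1),1,68290053,Maternal,Germ-line#,46.09,five_prime_upstream,Yes,YV,5.4,DIRAS3
ZDBF2,2,206834066,Paternal,Germ-line,47.65,intergenic,No,Y,1.4,
NAP1L5,4,89837958,Maternal,Germ-line,50.16,embedded_gene_promoter,No,N,7.2,
ZAC,6,144371274,Maternal,Germ-line,40.83,isoform_promoter,Yes,N,11.2,
IGF2R-2,6,160346534,Unknown,Unknown,81.34,gene_body_intronic,Yes,N,6.6,IGF2R
SLC22A1,6,160475377,Unknown,Unknown,82.78,gene_body_exonic,Yes,N,5.6,IGF2R
SLC22A3,6,160688909,Unknown,Unknown,39.89,promoter,Yes,YV,7.6,IGF2R
MEST (s),7,129913465,Maternal,Somatic,28.15,isoform_promoter,Yes,Y,8.2,MEST
MEST,7,129918562,Maternal,Germ-line,45.84,isoform_promoter,Yes,Y,7,MEST
GRB10 (g),7,50817567,Maternal,Germ-line,45.47,isoform_promoter,Yes,YV,12.6,GRB10
GRB10 (s),7,50829108,Maternal,Somatic,19.19,isoform_promoter,Yes,YV,6,GRB10
PEG10,7,94123850,Maternal,Germ-line,55.63,promoter,Yes,Y,6.4,PEG10
PON1,7,94791675,Unknown,Unknown,34.04,promoter,Yes,N,4.6,PEG10
INPP5FV2,10,121568151,Maternal,Germ-line,60.89,isoform_promoter,Yes,YV,11.2,
H19 DMR,11,1977714,Paternal,Germ-line,45.23,five_prime_upstream,No,Y,5.8,H19_IGF2
IGF2 (2),11,2110885,Paternal,Somatic,35.41,gene_body_exonic,Yes,N,6.2,H19_IGF2
IGF2 (0),11,2126069,Paternal,Somatic,54.59,isoform_promoter,No,N,2.2,H19_IGF2
KCNQ1,11,2422247,Unknown,Unknown,22.27,five_prime_upstream,Yes,YV,6.8,KCNQ1
KvDMR,11,2678628,Maternal,Germ-line,50.68,antisense_promoter,Yes,YV,5.6,KCNQ1
KCNQ1DN,11,2847182,Unknown,Unknown,26.22,five_prime_upstream,Yes,N,11.4,KCNQ1
CDKN1C,11,2861764,None,None,12.07,gene_body_exonic,Yes,Y,10.8,KCNQ1
OSBPL5 (3),11,3098345,Unknown,Unknown,82.66,gene_body_exonic,Yes,N,4.2,KCNQ1
RB1,13,47791152,Maternal,Germ-line,59.47,gene_body_intronic,Yes,N,6.4,
DLK,14,100262671,Paternal,Somatic,56.05,promoter,Yes,N,9.2,DLK1_MEG3
IG-DMR,14,100345582,Paternal,Germ-line,58.17,intergenic,No,N,2.4,DLK1_MEG3
MEG3-US,14,100360453,Paternal,Somatic,49.55,intergenic,Yes,N,6.6,DLK1_MEG3
MEG3,14,100361829,Paternal,Somatic,48.99,promoter,Yes,YV,6.2,DLK1_MEG3
RTL,14,100419312,None,None,88.27,gene_body_exonic,Yes,N,6.4,DLK1_MEG3
MKRN3,15,21362387,Unknown,Unknown,62.44,gene_body_exonic,No,N,4.4,PWS_AS
SNRPN,15,22751911,Maternal,Germ-line,47.12,isoform_promoter,Yes,N,7.8,PWS_AS
UBE3A,15,23234499,None,None,3.15,promoter,Yes,Y,9.6,PWS_AS
ATP10A,15,23658720,None,None,13.82,promoter,Yes,N,5.4,PWS_AS
GABRB3,15,24425436,Unknown,Unknown,47.8,isoform_promoter,Yes,YV,7.6,PWS_AS
GABRA5,15,24663372,Unknown,Unknown,87.29,promoter,Yes,YV,13,PWS_AS
TCEB3C,18,42797692,None,None,86.52,embedded_gene_promoter,Yes,YV,7.6,
NLRP2,19,60186163,Unknown,Unknown,61.93,gene_body_exonic,Yes,N,7,
PEG3/ZIM2,19,62043527,Maternal,Germ-line,49.92,gene_body_intronic,Yes,N,9.2,PEG3
USP29,19,62322335,Unknown,Unknown,43.27,intergenic,Yes,N,7.4,PEG3
ZIM3,19,62348129,Unknown,Unknown,74.21,promoter,No,N,1,PEG3
MCTS2,20,21441323,Maternal,Germ-line,44.72,embedded_gene_promoter,Yes,Y,6.6,
NNAT,20,35582455,Maternal,Germ-line,77.93,embedded_gene_promoter,Yes,YV,5.2,NNAT_BLCAP
BLCAP,20,35589631,None,None,8.37,promoter,Yes,YV,7.6,NNAT_BLCAP
L3MBTL,20,41576732,Maternal,Germ-line,51.23,gene_body_exonic,Yes,Y,7.6,
NESP,20,56848977,Paternal,Somatic,45.7,isoform_promoter,Yes,Y,9.2,GNAS
NESPAS,20,56860398,Maternal,Somatic,47.53,isoform_promoter,Yes,N,6.4,GNAS
GNAS XL,20,56864018,Maternal,Germ-line,43.98,isoform_promoter,Yes,N,5.6,GNAS
GNAS 1A,20,56898576,Maternal,Somatic,25.1,isoform_promoter,Yes,N,12,GNAS
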