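method,condition,gene,coexpressed_tlrs,common_neighbors,tlrs_in_cluster
pearson,treated-inactive,BCL6,4,4,4
pearson,treated-inactive,CCL5,5,6,0
pearson,treated-inactive,FOXP3,3,4,0
pearson,treated-inactive,GATA3,3,4,0
pearson,treated-inactive,CD28,2,4,0
pearson,treated-inactive,T-bet,3,3,0
pearson,treated-inactive,NR4A1,3,2,1
pearson,treated-inactive,CD3,1,3,0
pearson,treated-inactive,CD40,0,0,4
pearson,treated-inactive,TIGIT,0,3,1
pearson,treated-inactive,TCR,0,3,0
pearson,treated-inactive,CD40L,0,3,0
pearson,treated-inactive,CTLA4,0,2,0
pearson,treated-inactive,PD-1,1,0,1
pearson,treated-inactive,PD-L2,0,2,0
pearson,treated-inactive,TIM3,0,1,1
pearson,treated-inactive,CD83,0,1,0
pearson,treated-inactive,IkBa,0,1,0
pearson,treated-inactive,P50,0,1,0
pearson,treated-inactive,RORC,0,1,0
pearson,treated-inactive,LAG3,0,0,1
pearson,treated-inactive,TNF,0,1,0
pearson,treated-inactive,P65,0,0,0
pearson,treated-inactive,PD-L1,0,0,0
spearman,treated-inactive,BCL6,4,8,4
spearman,treated-inactive,TIGIT,4,6,4
spearman,treated-inactive,IkBa,4,5,4
spearman,treated-inactive,NR4A1,2,6,4
spearman,treated-inactive,FOXP3,3,8,0
spearman,treated-inactive,CCL5,5,5,0
spearman,treated-inactive,CD28,3,6,0
spearman,treated-inactive,GATA3,3,4,0
spearman,treated-inactive,T-bet,3,2,0
spearman,treated-inactive,TCR,1,4,0
spearman,treated-inactive,CD40L,0,5,0
spearman,treated-inactive,CD83,1,3,0
spearman,treated-inactive,PD-L2,0,3,1
spearman,treated-inactive,LAG3,0,0,4
spearman,treated-inactive,TNF,1,3,0
spearman,treated-inactive,CD3,0,2,0
spearman,treated-inactive,P50,0,2,0
spearman,treated-inactive,CD40,0,1,0
spearman,treated-inactive,CTLA4,0,1,0
spearman,treated-inactive,PD-L1,0,1,0
spearman,treated-inactive,P65,0,0,0
spearman,treated-inactive,PD-1,0,0,0
spearman,treated-inactive,RORC,0,0,0
spearman,treated-inactive,TIM3,0,0,0
pearson,treated-active,BCL6,2,0,5
pearson,treated-active,PD-1,0,1,0
pearson,treated-active,LAG3,0,1,0
pearson,treated-active,CD28,0,0,0
pearson,treated-active,CD3,0,0,0
pearson,treated-active,CD40,0,0,0
pearson,treated-active,CD83,0,0,0
pearson,treated-active,CTLA4,0,0,0
pearson,treated-active,FOXP3,0,0,0
pearson,treated-active,GATA3,0,0,0
pearson,treated-active,IkBa,0,0,0
pearson,treated-active,P50,0,0,0
pearson,treated-active,P65,0,0,0
pearson,treated-active,PD-L1,0,0,0
pearson,treated-active,PD-L2,0,0,0
pearson,treated-active,RORC,0,0,0
pearson,treated-active,T-bet,0,0,0
pearson,treated-active,TCR,0,0,0
pearson,treated-active,TIGIT,0,0,0
pearson,treated-active,TIM3,0,0,0
pearson,treated-active,CCL5,0,0,0
pearson,treated-active,CD40L,0,0,0
pearson,treated-active,TNF,0,0,0
pearson,treated-active,NR4A1,0,0,0
spearman,treated-active,BCL6,0,1,2
spearman,treated-active,CD40,0,1,2
spearman,treated-active,LAG3,1,0,2
spearman,treated-active,PD-L2,0,0,2
spearman,treated-active,CD83,1,0,0
spearman,treated-active,IkBa,1,0,0
spearman,treated-active,P50,0,1,0
spearman,treated-active,TIGIT,0,1,0
spearman,treated-active,TIM3,0,1,0
spearman,treated-active,TNF,0,1,0
spearman,treated-active,NR4A1,0,1,0
spearman,treated-active,CD28,0,0,0
spearman,treated-active,CD3,0,0,0
spearman,treated-active,CTLA4,0,0,0
spearman,treated-active,FOXP3,0,0,0
spearman,treated-active,GATA3,0,0,0
spearman,treated-active,P65,0,0,0
spearman,treated-active,PD-1,0,0,0
spearman,treated-active,PD-L1,0,0,0
spearman,treated-active,RORC,0,0,0
spearman,treated-active,T-bet,0,0,0
spearman,treated-active,TCR,0,0,0
spearman,treated-active,CCL5,0,0,0
spearman,treated-active,CD40L,0,0,0
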